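"""Cross-mapping correction: distributing multi-mapped read counts across
near-identical loci by iterative proportional reassignment, plus the
missed-read and discard rules.

A read mapping to several loci starts with a uniform weight over them; at
each iteration its weight at a locus is set proportional to that locus's
expression (the weighted read count over the locus's footprint window) and
renormalised, until the weights stop changing.  Loci that attract more
uniquely mapping reads therefore absorb more of the shared reads — the
standard proportional resolution of short-read cross-mapping ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
DEFAULT_MAX_LOCI = 100
#: Reads whose cross-mapping weight falls below this are treated as unlikely
#: to originate from the locus (used by pseudo-site detection downstream).
DEFAULT_PSEUDO_WEIGHT = 0.05


@dataclass(frozen=True, order=True)
class Locus:
    """A read footprint on the reference: chromosome interval plus strand."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class LocusWeight:
    read_id: str
    locus: Locus
    weight: float


def assign_weights(
    placements: Mapping[str, Sequence[Locus]],
    counts: Mapping[str, float],
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> dict[str, dict[Locus, float]]:
    """Iteratively reassign each multi-mapped read's count across its loci.

    ``placements`` maps read id -> loci the read maps to; ``counts`` carries
    the read's library multiplicity.  The expression of a locus is the sum of
    ``count * weight`` over all read placements whose footprints overlap it
    (a window equal to the read footprint).  Weights of a read are
    renormalised to sum to 1 each iteration; iteration stops when the largest
    absolute weight change drops below ``tol``.  Non-convergence after
    ``max_iter`` iterations raises a warning and returns the last iterate.
    """
    read_ids = sorted(placements)
    for rid in read_ids:
        if not placements[rid]:
            raise ValueError(f"read {rid!r} has no loci")

    # Flat arrays over all (read, locus) placements, grouped by chrom/strand.
    entries: list[tuple[str, Locus]] = [
        (rid, locus) for rid in read_ids for locus in placements[rid]
    ]
    n_entries = len(entries)
    weight = np.empty(n_entries)
    count = np.empty(n_entries)
    read_slices: dict[str, slice] = {}
    pos = 0
    for rid in read_ids:
        k = len(placements[rid])
        read_slices[rid] = slice(pos, pos + k)
        weight[pos : pos + k] = 1.0 / k
        count[pos : pos + k] = float(counts[rid])
        pos += k

    groups: dict[tuple[str, str], list[int]] = {}
    for idx, (_, locus) in enumerate(entries):
        groups.setdefault((locus.chrom, locus.strand), []).append(idx)
    group_arrays = {}
    for key, idxs in groups.items():
        arr = np.asarray(idxs)
        starts = np.asarray([entries[i][1].start for i in idxs])
        ends = np.asarray([entries[i][1].end for i in idxs])
        group_arrays[key] = (arr, starts, ends)

    multi = [rid for rid in read_ids if len(placements[rid]) > 1]
    if multi:
        converged = False
        for _ in range(max_iter):
            value = count * weight
            delta = 0.0
            for rid in multi:
                sl = read_slices[rid]
                expr = np.empty(sl.stop - sl.start)
                for k, idx in enumerate(range(sl.start, sl.stop)):
                    locus = entries[idx][1]
                    arr, starts, ends = group_arrays[(locus.chrom, locus.strand)]
                    mask = (starts <= locus.end) & (ends >= locus.start)
                    expr[k] = value[arr[mask]].sum()
                total = expr.sum()
                new = expr / total if total > 0 else np.full_like(expr, 1 / len(expr))
                delta = max(delta, float(np.abs(new - weight[sl]).max()))
                weight[sl] = new
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"cross-mapping weights did not converge within {max_iter} "
                f"iterations (last max change {delta:.2e})",
                RuntimeWarning,
            )

    return {
        rid: {
            locus: float(weight[read_slices[rid].start + k])
            for k, locus in enumerate(placements[rid])
        }
        for rid in read_ids
    }


def resolve_missed_read(
    hairpin_hits: Sequence[tuple[object, float]],
    genome_hits: Sequence[tuple[object, float]] = (),
    max_loci: int = DEFAULT_MAX_LOCI,
) -> dict[object, float]:
    """Weights for a read that aligns to a hairpin but is absent from the
    cross-mapping result.

    Each hit is a ``(locus, alignment score)`` pair.  The read is neglected
    (empty mapping, weight 0 everywhere) when a genomic locus outscores its
    best hairpin alignment, or when more than ``max_loci`` equal-scoring loci
    exist.  Otherwise the read's count is divided evenly across its
    best-scoring mapped loci.
    """
    if not hairpin_hits:
        return {}
    best = max(score for _, score in hairpin_hits)
    if any(score > best for _, score in genome_hits):
        return {}
    eligible = [locus for locus, score in hairpin_hits if score == best]
    eligible += [locus for locus, score in genome_hits if score == best]
    if len(eligible) > max_loci:
        return {}
    share = 1.0 / len(eligible)
    return {locus: share for locus in eligible}


def weights_table(weights: Mapping[str, Mapping[Locus, float]]) -> pd.DataFrame:
    """Flatten a weight mapping into an audit table (read_id, locus, weight)."""
    rows = [
        {
            "read_id": rid,
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "strand": locus.strand,
            "weight": w,
        }
        for rid in sorted(weights)
        for locus, w in sorted(weights[rid].items())
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "start", "end", "strand", "weight"]
    )
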