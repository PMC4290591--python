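"""Per-position evidence tallies, significance testing and classification of
mutation/editing (M/E) sites on pre-miRNA hairpins.

For every hairpin position carrying non-reference reads the pipeline forms a
weighted tally: ``n`` is the cross-mapping-weighted read coverage of the
position (bases below the phred threshold excluded), ``mer`` the weighted
count of reads carrying the alternative nucleotide, and ``p_o = mer / n`` the
observed M/E fraction.  Against the expected sequencing-error rate ``p_e``
the site is scored with the one-sample proportion statistic

    Z = (p_o - p_e) / sqrt(p_e * (1 - p_e) / n)

whose upper tail under the standard normal gives the site p-value; p-values
are Benjamini-Hochberg corrected within each library.  A significant site
needs at least ``min_reads`` supporting reads, an M/E fraction of at least
``min_fraction`` and a corrected p-value below ``alpha``.  Sites are then
classified into eight categories: 3'-A, 3'-U, 3'-Other, A-to-I, C-to-U, SNP,
Other and Pseudo (sites whose significance evaporates once low-weight
multi-mapped reads are removed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .crossmap import DEFAULT_PSEUDO_WEIGHT
from .formats_io import Hairpin, QualityRead, SNPRecord, to_dna, to_rna
from .hairpin_align import (
    DELETION,
    INSERTION,
    MATCH,
    MISMATCH,
    SOFT,
    AlignmentHit,
    tail_extend_columns,
)

CATEGORIES = ("3'-A", "3'-U", "3'-Other", "A-to-I", "C-to-U", "SNP", "Other", "Pseudo")

DEFAULT_MIN_READS = 10
DEFAULT_MIN_FRACTION = 0.05
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_PHRED = 20
#: Error-rate floor; makes the test conservative on collapsed inputs whose
#: qualities are synthetic constants (phred 20 corresponds to 1% error).
DEFAULT_PE_FLOOR = 0.01
#: Positions up to this far beyond a mature 3' end count as the 3'-tail
#: region for classification.
DEFAULT_TAIL_WINDOW = 6


def phred_to_error(q: int) -> float:
    """Expected per-base error probability for a phred score: 10^(-q/10)."""
    if q < 0:
        raise ValueError("phred score must be >= 0")
    return 10.0 ** (-q / 10.0)


def z_statistic(p_o: float, p_e: float, n: float) -> tuple[float, float]:
    """Proportion Z statistic and its one-sided (upper-tail) normal p-value.

    One-sided because an excess of non-reference reads over the error rate is
    the only alternative of interest.
    """
    if n <= 0:
        raise ValueError("site has no supporting coverage (n must be > 0)")
    if not 0.0 < p_e < 1.0:
        raise ValueError("expected error rate must lie strictly in (0, 1)")
    z = (p_o - p_e) / math.sqrt(p_e * (1.0 - p_e) / n)
    return z, float(stats.norm.sf(z))


def bh_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    if len(p_values) == 0:
        return []
    arr = np.asarray(p_values, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


@dataclass
class PositionTally:
    """Weighted per-position evidence for one candidate alternative allele."""

    hairpin_id: str
    position: int  # 1-based hairpin coordinate
    ref: str  # reference nucleotide, or "-" for read-borne insertions
    alt: str
    n: float  # weighted coverage
    mer: float  # weighted count of reads carrying alt
    p_e: float
    library: str = ""
    z: float = float("nan")
    p_value: float = 1.0
    fdr_p: float = 1.0

    @property
    def p_o(self) -> float:
        return self.mer / self.n if self.n > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.hairpin_id, self.position, self.ref, self.alt)


@dataclass
class MESite:
    """A called M/E site with its per-library tallies."""

    me_id: str
    hairpin_id: str
    position: int
    ref: str
    alt: str
    category: str
    position_in_mature: Optional[int] = None
    tallies: dict[str, PositionTally] = field(default_factory=dict)
    significant_in: tuple[str, ...] = ()
    known_editing: str = ""


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PileupRead:
    """One aligned read contributing to a hairpin pileup."""

    read: QualityRead
    hit: AlignmentHit
    weight: float


def position_is_3prime(
    hairpin: Hairpin, position: int, tail_window: int = DEFAULT_TAIL_WINDOW
) -> bool:
    """Whether a hairpin position belongs to the 3'-tail region of a mature
    arm: strictly beyond a mature 3' end (within ``tail_window`` bases) or
    beyond the templated hairpin end, and inside no mature interval."""
    if position > len(hairpin):
        return True
    if hairpin.mature_position(position) is not None:
        return False
    return any(
        iv.end < position <= iv.end + tail_window for iv in hairpin.mature_intervals
    )


def pileup(
    hairpin: Hairpin,
    placements: Sequence[PileupRead],
    min_phred: int = DEFAULT_MIN_PHRED,
    pe_floor: float = DEFAULT_PE_FLOOR,
    tail_window: int = DEFAULT_TAIL_WINDOW,
    library: str = "",
) -> list[PositionTally]:
    """Weighted per-position tallies over a hairpin.

    Each aligned read contributes ``count * weight`` to the coverage of every
    position where its base scores at least ``min_phred``; mismatch columns
    feed the matching (position, alt) tally; insertion columns create tallies
    with ref "-" at the position following the last matched base; unaligned
    3' read tails are re-attached as extension columns so non-templated
    additions are observed (SOFT columns beyond the hairpin end included).
    In the 3'-tail region a read whose alignment stops at the previous
    position additionally counts toward coverage: a read ending exactly at
    the mature 3' end is direct evidence of an unmodified 3' end.

    ``p_e`` per tally is the coverage-weighted mean phred-derived error at the
    position, floored at ``pe_floor``.
    """
    coverage: dict[int, float] = {}
    err_sum: dict[int, float] = {}
    alt_counts: dict[tuple[int, str, str], float] = {}

    for pr in placements:
        read, hit, w = pr.read, pr.hit, pr.weight
        if w <= 0.0:
            continue
        value = read.count * w
        columns = list(hit.columns) + list(
            tail_extend_columns(hit, read.sequence, hairpin.sequence)
        )
        seen_insertions: set[tuple[int, str, str]] = set()
        last_pos = 0
        prev_target = hit.target_start - 1
        for col in columns:
            if col.kind == DELETION:
                prev_target = col.target_pos
                continue
            q = read.phred[col.read_pos - 1]
            err = phred_to_error(q)
            if col.kind == INSERTION:
                if q < min_phred:
                    continue
                key = (prev_target + 1, "-", col.read_nt)
                if key not in seen_insertions:
                    alt_counts[key] = alt_counts.get(key, 0.0) + value
                    seen_insertions.add(key)
                continue
            pos = col.target_pos
            prev_target = pos
            if q < min_phred:
                continue
            coverage[pos] = coverage.get(pos, 0.0) + value
            err_sum[pos] = err_sum.get(pos, 0.0) + value * err
            last_pos = max(last_pos, pos)
            if col.kind == MISMATCH:
                key = (pos, col.target_nt, col.read_nt)
                alt_counts[key] = alt_counts.get(key, 0.0) + value
            elif col.kind == SOFT:
                key = (pos, "-", col.read_nt)
                alt_counts[key] = alt_counts.get(key, 0.0) + value
        # terminator evidence: a read ending just before a 3'-tail position
        # documents the absence of a non-templated addition there
        term = last_pos + 1
        if last_pos > 0 and position_is_3prime(hairpin, term, tail_window):
            q = read.phred[-1]
            if q >= min_phred:
                coverage[term] = coverage.get(term, 0.0) + value
                err_sum[term] = err_sum.get(term, 0.0) + value * phred_to_error(q)

    tallies: list[PositionTally] = []
    for (pos, ref, alt), mer in sorted(alt_counts.items()):
        if alt not in "ACGT":
            continue
        if ref != "-" and ref not in "ACGT":
            continue
        n = coverage.get(pos, 0.0)
        if ref == "-" and pos <= len(hairpin):
            # insertion between pos-1 and pos: denominator is reads aligned at pos
            n = coverage.get(pos, 0.0)
        if n <= 0.0:
            continue
        mer = min(mer, n)
        p_e = max(err_sum.get(pos, 0.0) / n if n > 0 else pe_floor, pe_floor)
        z, p = z_statistic(mer / n, p_e, n)
        tallies.append(
            PositionTally(
                hairpin_id=hairpin.hairpin_id,
                position=pos,
                ref=ref,
                alt=alt,
                n=n,
                mer=mer,
                p_e=p_e,
                library=library,
                z=z,
                p_value=p,
            )
        )
    return tallies


# ---------------------------------------------------------------------------
# calling, classification, naming
# ---------------------------------------------------------------------------


def call_significant(
    tallies: Sequence[PositionTally],
    min_reads: float = DEFAULT_MIN_READS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    apply_bh: bool = True,
) -> list[PositionTally]:
    """Significant sites among one library's candidate tallies.

    BH correction is applied across the whole candidate family first; a site
    is retained when its weighted supporting count reaches ``min_reads``, its
    M/E fraction reaches ``min_fraction`` and its corrected p-value is below
    ``alpha``.  Sites in the last positions of the mature 3' end are *not*
    excluded: 3'-end editing is part of what the pipeline looks for.
    """
    if apply_bh:
        adjusted = bh_correct([t.p_value for t in tallies])
        for tally, fdr in zip(tallies, adjusted):
            tally.fdr_p = float(fdr)
    return [
        t
        for t in tallies
        if t.mer >= min_reads and t.p_o >= min_fraction and t.fdr_p < alpha
    ]


def passes_criteria(
    tally: Optional[PositionTally],
    min_reads: float = DEFAULT_MIN_READS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    use_raw_p: bool = False,
) -> bool:
    """Whether a single tally satisfies the calling criteria (raw p-value
    compared against alpha when ``use_raw_p``, e.g. during the pseudo-site
    recomputation where the BH family is not re-formed)."""
    if tally is None or tally.n <= 0:
        return False
    p = tally.p_value if use_raw_p else tally.fdr_p
    return tally.mer >= min_reads and tally.p_o >= min_fraction and p < alpha


def classify(
    tally: PositionTally,
    hairpin: Hairpin,
    snp_table: Iterable[SNPRecord] | Mapping[tuple, SNPRecord] | None = None,
    filtered_tally: Optional[PositionTally] = None,
    check_pseudo: bool = False,
    min_reads: float = DEFAULT_MIN_READS,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    tail_window: int = DEFAULT_TAIL_WINDOW,
) -> str:
    """Category of a significant site, by the decision order:

    1. **Pseudo** — the site stops satisfying the calling criteria once reads
       with sub-threshold cross-mapping weight are removed
       (``filtered_tally`` is the site's tally recomputed without them;
       enable via ``check_pseudo``);
    2. **SNP** — (hairpin, position, ref, alt) matches the known-SNP table;
    3. **3'-A / 3'-U / 3'-Other** — the site lies in the 3'-tail region of a
       mature arm (or beyond the hairpin end), split by the added nucleotide;
    4. **A-to-I** — ref A, alt g (inosine reads as G);
    5. **C-to-U** — ref C, alt u;
    6. **Other** — everything else, including read-borne insertions.
    """
    ref = "-" if tally.ref == "-" else to_dna(tally.ref)
    alt = to_dna(tally.alt)
    if ref != "-" and ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"unknown nucleotides ref={tally.ref!r} alt={tally.alt!r}")
    if check_pseudo and not passes_criteria(
        filtered_tally, min_reads, min_fraction, alpha, use_raw_p=True
    ):
        return "Pseudo"
    if snp_table is not None:
        items = snp_table.keys() if isinstance(snp_table, Mapping) else snp_table
        keys = {
            item.key if isinstance(item, SNPRecord) else tuple(item)
            for item in items
        }
        if (tally.hairpin_id, tally.position, ref, alt) in keys:
            return "SNP"
    if position_is_3prime(hairpin, tally.position, tail_window):
        if alt == "A":
            return "3'-A"
        if alt == "T":
            return "3'-U"
        return "3'-Other"
    if ref == "A" and alt == "G":
        return "A-to-I"
    if ref == "C" and alt == "T":
        return "C-to-U"
    return "Other"


def name_site(hairpin_id: str, position: int, ref: str, alt: str) -> str:
    """Canonical site name: ``{hairpin}_{position}_{REF}_{alt}`` with the
    reference upper-case RNA (or "-" for insertions) and the alternative
    lower-case RNA, e.g. ``hsa-mir-376a-1_49_A_g``."""
    ref_r = "-" if ref == "-" else to_rna(ref).upper()
    alt_r = to_rna(alt).lower()
    if ref_r not in ("A", "C", "G", "U", "-"):
        raise ValueError(f"invalid reference nucleotide {ref!r}")
    if alt_r not in ("a", "c", "g", "u"):
        raise ValueError(f"invalid alternative nucleotide {alt!r}")
    if ref_r == alt_r.upper():
        raise ValueError(f"reference and alternative are identical ({ref!r})")
    if position < 1:
        raise ValueError("position must be >= 1")
    return f"{hairpin_id}_{position}_{ref_r}_{alt_r}"


def merge_libraries(
    significant: Mapping[str, Sequence[tuple[PositionTally, str]]],
    all_tallies: Mapping[str, Sequence[PositionTally]],
    hairpins: Mapping[str, Hairpin],
    editing_table: Optional[Mapping[tuple, str]] = None,
) -> tuple[list[MESite], int]:
    """Union of per-library significant sites, keyed by canonical name.

    Every library's tally is attached (absent libraries contribute nothing
    and are rendered as zeros by the report writer).  When libraries disagree
    on the category, the category from the library with the smallest
    corrected p-value wins.  Returns the merged sites (sorted by hairpin and
    position) and the number of sites significant in every library.
    """
    libraries = list(significant)
    tally_lookup: dict[str, dict[tuple, PositionTally]] = {
        lib: {t.key: t for t in all_tallies.get(lib, ())} for lib in libraries
    }
    merged: dict[str, MESite] = {}
    categories: dict[str, list[tuple[float, str, str]]] = {}
    for lib in libraries:
        for tally, category in significant[lib]:
            me_id = name_site(tally.hairpin_id, tally.position, tally.ref, tally.alt)
            if me_id not in merged:
                hairpin = hairpins[tally.hairpin_id]
                mature = (
                    hairpin.mature_position(tally.position)
                    if tally.position <= len(hairpin)
                    else None
                )
                ref = "-" if tally.ref == "-" else to_dna(tally.ref)
                alt = to_dna(tally.alt)
                merged[me_id] = MESite(
                    me_id=me_id,
                    hairpin_id=tally.hairpin_id,
                    position=tally.position,
                    ref=ref,
                    alt=alt,
                    category=category,
                    position_in_mature=mature[1] if mature else None,
                    known_editing=(
                        (editing_table or {}).get(
                            (tally.hairpin_id, tally.position, ref, alt), ""
                        )
                    ),
                )
            site = merged[me_id]
            site.significant_in = tuple(
                sorted(set(site.significant_in) | {lib})
            )
            categories.setdefault(me_id, []).append((tally.fdr_p, lib, category))
    for me_id, site in merged.items():
        votes = categories[me_id]
        if len({cat for _, _, cat in votes}) > 1:
            site.category = min(votes)[2]
        for lib in libraries:
            tally = tally_lookup[lib].get(
                (site.hairpin_id, site.position, site.ref, site.alt)
            )
            if tally is not None:
                site.tallies[lib] = tally
    sites = sorted(merged.values(), key=lambda s: (s.hairpin_id, s.position, s.alt))
    n_common = sum(
        1 for s in sites if set(s.significant_in) == set(libraries)
    )
    return sites, n_common


def category_counts(sites: Sequence[MESite], libraries: Sequence[str]):
    """Per-library and union counts of significant sites per category."""
    import pandas as pd

    rows = []
    for category in CATEGORIES:
        of_cat = [s for s in sites if s.category == category]
        row = {"category": category}
        for lib in libraries:
            row[lib] = sum(1 for s in of_cat if lib in s.significant_in)
        row["union"] = len(of_cat)
        rows.append(row)
    return pd.DataFrame(rows, columns=["category", *libraries, "union"])
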