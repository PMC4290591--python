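"""Local alignment of small-RNA reads to pre-miRNA hairpins, and genome-locus
enumeration for cross-mapping bookkeeping.

The aligner is an affine-gap Smith-Waterman with the scoring used throughout
the pipeline: +4 per match, -3 per mismatch, and a gap of length ``k`` costing
``gap_open + k * gap_extend`` (default -4 - 2k): opening is a fee separate
from the per-base extension.  Candidate hairpins are found by exact k-mer
seeding; genome loci are exact occurrences of the read on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .formats_io import Hairpin, revcomp

NEG_INF = float("-inf")

MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion_in_read"
DELETION = "deletion_from_read"
SOFT = "soft"  # read base beyond the templated 3' end of the target


@dataclass(frozen=True)
class ScoringScheme:
    match_reward: int = 4
    mismatch_penalty: int = -3
    gap_open: int = -4
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match reward must be positive")
        if max(self.mismatch_penalty, self.gap_open, self.gap_extend) >= 0:
            raise ValueError("penalties must be negative")

    def substitution(self, a: str, b: str) -> int:
        return self.match_reward if a == b else self.mismatch_penalty

    def gap_cost(self, length: int) -> int:
        """Total cost of a gap of ``length`` bases (open fee plus extension)."""
        return self.gap_open + length * self.gap_extend


DEFAULT_SCHEME = ScoringScheme()

#: Default minimum score for retaining a read-to-hairpin hit
#: (roughly a 14-nt perfect core under the default scheme).
DEFAULT_MIN_SCORE = 50
DEFAULT_SEED_K = 12
DEFAULT_MAX_LOCI = 100


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of a gapped alignment; positions are 1-based or None for a
    gap on that side."""

    target_pos: Optional[int]
    read_pos: Optional[int]
    target_nt: str
    read_nt: str
    kind: str


@dataclass(frozen=True)
class AlignmentHit:
    """One gapped local alignment of a read to a hairpin or genome locus."""

    read_id: str
    target_id: str
    target_start: int  # 1-based inclusive
    target_end: int
    strand: str
    score: int
    columns: tuple[AlignmentColumn, ...] = ()

    @property
    def read_span(self) -> tuple[int, int]:
        """1-based first and last read positions covered by the alignment."""
        positions = [c.read_pos for c in self.columns if c.read_pos is not None]
        return (min(positions), max(positions)) if positions else (0, 0)


class Discarded:
    """Marker returned for reads mapping to more genomic loci than allowed."""

    def __repr__(self) -> str:  # pragma: no cover
        return "DISCARDED"


DISCARDED = Discarded()


def score_columns(columns: Sequence[AlignmentColumn], scheme: ScoringScheme) -> int:
    """Recompute an alignment score from its columns with affine gap
    accounting (used as an integrity check; SOFT columns score 0)."""
    total = 0
    in_gap = False
    for col in columns:
        if col.kind in (MATCH, MISMATCH):
            total += scheme.substitution(col.target_nt, col.read_nt)
            in_gap = False
        elif col.kind in (INSERTION, DELETION):
            total += scheme.gap_extend if in_gap else scheme.gap_open + scheme.gap_extend
            in_gap = True
        elif col.kind == SOFT:
            in_gap = False
    return total


def local_align(
    read: str,
    target: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_score: Optional[int] = None,
    read_id: str = "",
    target_id: str = "",
) -> Optional[AlignmentHit]:
    """Optimal affine-gap local alignment of ``read`` against ``target``.

    Three-state dynamic programming (substitution / gap-in-read /
    gap-in-target); a gap of length k costs ``gap_open + k * gap_extend``.
    Returns None when no alignment scores above 0 (or above ``min_score``
    when given).  Traceback ties prefer substitution over deletion-from-read
    over insertion-in-read, giving a deterministic single alignment.
    """
    if not read or not target:
        return None
    m, n = len(read), len(target)
    open_cost = scheme.gap_open + scheme.gap_extend
    ext = scheme.gap_extend

    # M: read[i-1] aligned to target[j-1]; D: gap in read (consumes target);
    # I: gap in target (consumes read).
    M = [[0.0] * (n + 1) for _ in range(m + 1)]
    D = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    I = [[NEG_INF] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        ri = read[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Di, Di1 = D[i], D[i - 1]
        Ii, Ii1 = I[i], I[i - 1]
        for j in range(1, n + 1):
            diag = max(Mi1[j - 1], Di1[j - 1], Ii1[j - 1], 0.0)
            Mi[j] = diag + scheme.substitution(ri, target[j - 1])
            Di[j] = max(Mi[j - 1] + open_cost, Di[j - 1] + ext, Ii[j - 1] + open_cost)
            Ii[j] = max(Mi1[j] + open_cost, Ii1[j] + ext, Di1[j] + open_cost)
            if Mi[j] > best:
                best, bi, bj = Mi[j], i, j
    threshold = 1 if min_score is None else min_score
    if best < threshold:
        return None

    # Traceback from the best substitution cell.
    columns: list[AlignmentColumn] = []
    i, j, state = bi, bj, "M"
    while i > 0 and j > 0:
        if state == "M":
            columns.append(
                AlignmentColumn(
                    j, i, target[j - 1], read[i - 1],
                    MATCH if read[i - 1] == target[j - 1] else MISMATCH,
                )
            )
            sub = M[i][j] - scheme.substitution(read[i - 1], target[j - 1])
            i, j = i - 1, j - 1
            if sub == 0:
                break  # local start
            # tie-break: substitution > deletion-from-read > insertion-in-read
            if M[i][j] == sub:
                state = "M"
            elif D[i][j] == sub:
                state = "D"
            elif I[i][j] == sub:
                state = "I"
            else:
                break  # local start
        elif state == "D":
            columns.append(AlignmentColumn(j, None, target[j - 1], "-", DELETION))
            here = D[i][j]
            j -= 1
            if M[i][j] + open_cost == here:
                state = "M"
            elif D[i][j] + ext == here:
                state = "D"
            else:
                state = "I"
        else:  # state == "I"
            columns.append(AlignmentColumn(None, i, "-", read[i - 1], INSERTION))
            here = I[i][j]
            i -= 1
            if M[i][j] + open_cost == here:
                state = "M"
            elif I[i][j] + ext == here:
                state = "I"
            else:
                state = "D"
    columns.reverse()
    target_positions = [c.target_pos for c in columns if c.target_pos is not None]
    return AlignmentHit(
        read_id=read_id,
        target_id=target_id,
        target_start=min(target_positions),
        target_end=max(target_positions),
        strand="+",
        score=int(best),
        columns=tuple(columns),
    )


def tail_extend_columns(
    hit: AlignmentHit, read: str, target: str
) -> tuple[AlignmentColumn, ...]:
    """Extension columns for the read's unaligned 3' tail.

    Local alignment drops trailing mismatching bases (they lower the score),
    yet those bases are exactly where 3' non-templated additions live.  Each
    unaligned 3' read base is paired with the next target position (a match or
    mismatch column); bases running past the target's end become SOFT columns
    with target positions beyond ``len(target)``.
    """
    _, read_end = hit.read_span
    if read_end == 0 or read_end >= len(read):
        return ()
    out: list[AlignmentColumn] = []
    t = hit.target_end
    for rpos in range(read_end + 1, len(read) + 1):
        t += 1
        if t <= len(target):
            tnt = target[t - 1]
            kind = MATCH if read[rpos - 1] == tnt else MISMATCH
            out.append(AlignmentColumn(t, rpos, tnt, read[rpos - 1], kind))
        else:
            out.append(AlignmentColumn(t, rpos, "-", read[rpos - 1], SOFT))
    return tuple(out)


class KmerIndex:
    """Exact k-mer index over a hairpin collection, used to seed alignment.

    Guarantee: every hairpin sharing at least one exact k-mer with a query
    read is reported (a superset of the hairpins worth aligning to).
    """

    def __init__(
        self,
        hairpins: Mapping[str, Hairpin] | Mapping[str, str],
        k: int = DEFAULT_SEED_K,
    ) -> None:
        if k < 4:
            raise ValueError("seed length must be >= 4")
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for hid, hp in hairpins.items():
            seq = hp.sequence if isinstance(hp, Hairpin) else str(hp)
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((hid, pos))

    def candidates(self, read: str) -> list[tuple[str, int]]:
        """Hairpins sharing a k-mer with the read, with the seed diagonal
        (target_pos - read_pos, 0-based) for banded extension."""
        found: dict[tuple[str, int], None] = {}
        for rpos in range(len(read) - self.k + 1):
            for hid, tpos in self._index.get(read[rpos : rpos + self.k], ()):
                found[(hid, tpos - rpos)] = None
        return sorted(found)

    def candidate_ids(self, read: str) -> list[str]:
        return sorted({hid for hid, _ in self.candidates(read)})


def find_candidate_hairpins(
    read: str,
    hairpins: Mapping[str, Hairpin] | Mapping[str, str],
    k: int = DEFAULT_SEED_K,
) -> list[tuple[str, int]]:
    """Convenience wrapper building a throwaway :class:`KmerIndex`."""
    return KmerIndex(hairpins, k=k).candidates(read)


def _match_columns(
    read: str, start: int, strand: str, chrom_seq: str
) -> tuple[AlignmentColumn, ...]:
    cols = []
    L = len(read)
    for offset in range(L):
        tpos = start + offset
        rpos = offset + 1 if strand == "+" else L - offset
        cols.append(
            AlignmentColumn(tpos, rpos, chrom_seq[tpos - 1], chrom_seq[tpos - 1], MATCH)
        )
    return tuple(cols)


def map_to_genome(
    read: str,
    genome: Mapping[str, str],
    max_loci: int = DEFAULT_MAX_LOCI,
    read_id: str = "",
    with_columns: bool = False,
):
    """All exact end-to-end occurrences of the read in the genome, on both
    strands (reverse complement for '-').

    Returns a list of :class:`AlignmentHit`, or the :data:`DISCARDED` marker
    when the read occurs at more than ``max_loci`` loci.
    """
    hits: list[AlignmentHit] = []
    rc = revcomp(read)
    score = len(read) * DEFAULT_SCHEME.match_reward
    for chrom in sorted(genome):
        seq = genome[chrom]
        for query, strand in ((read, "+"), (rc, "-")):
            if strand == "-" and rc == read:
                continue  # palindromic read: forward hits already found
            start = seq.find(query)
            while start != -1:
                hits.append(
                    AlignmentHit(
                        read_id=read_id,
                        target_id=chrom,
                        target_start=start + 1,
                        target_end=start + len(query),
                        strand=strand,
                        score=score,
                        columns=(
                            _match_columns(read, start + 1, strand, seq)
                            if with_columns
                            else ()
                        ),
                    )
                )
                if len(hits) > max_loci:
                    return DISCARDED
                start = seq.find(query, start + 1)
    return hits


def read_bowtie_map(
    path, scheme: ScoringScheme = DEFAULT_SCHEME
) -> dict[str, list[AlignmentHit]]:
    """Import a Bowtie default-format alignment file as genome hits.

    Columns: read name, strand, reference, 0-based offset, read sequence,
    qualities, alignment ceiling, comma-separated mismatch descriptors.  Each
    mismatch swaps one match reward for the mismatch penalty in the hit score.
    This importer lets an external aligner replace the internal exact-match
    genome mapper for real genomes.
    """
    out: dict[str, list[AlignmentHit]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: not a Bowtie alignment line")
            name, strand, ref, offset, seq = fields[:5]
            descriptors = fields[7] if len(fields) > 7 else ""
            n_mismatch = len([d for d in descriptors.split(",") if d])
            score = (
                len(seq) * scheme.match_reward
                + n_mismatch * (scheme.mismatch_penalty - scheme.match_reward)
            )
            out.setdefault(name, []).append(
                AlignmentHit(
                    read_id=name,
                    target_id=ref,
                    target_start=int(offset) + 1,
                    target_end=int(offset) + len(seq),
                    strand=strand,
                    score=score,
                )
            )
    return out
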