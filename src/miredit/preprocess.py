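"""Raw-read preprocessing: 3' quality trimming, adapter removal and collapsing
of identical reads into unique sequences with counts.

The stage order mirrors standard small-RNA practice: low-quality 3' tails are
dealt with first (to give reads clean 3' ends), then the 3' sequencing adapter
is removed, then reads of at least ``min_len`` nucleotides are collapsed into
unique sequences carrying their library multiplicity.
"""

from __future__ import annotations

from typing import Iterable, Literal

from .formats_io import QualityRead

DEFAULT_MIN_PHRED = 20
DEFAULT_MIN_LEN = 18
DEFAULT_MISMATCH_RATE = 0.1
MIN_ADAPTER_OVERLAP = 5


def trim_low_quality_tail(read: QualityRead, min_phred: int = DEFAULT_MIN_PHRED) -> QualityRead:
    """Trim bases off the 3' end while the terminal base scores below
    ``min_phred``.  Internal low-quality bases are retained; the result may be
    an empty read."""
    end = len(read)
    while end > 0 and read.phred[end - 1] < min_phred:
        end -= 1
    if end == len(read):
        return read
    return QualityRead(read.read_id, read.sequence[:end], read.phred[:end], read.count)


def strip_adapter(
    read: QualityRead,
    adapter: str,
    max_mismatch_rate: float = DEFAULT_MISMATCH_RATE,
    min_overlap: int = MIN_ADAPTER_OVERLAP,
) -> QualityRead:
    """Cut the read at the leftmost occurrence of the 3' adapter.

    An occurrence is either the full adapter anywhere in the read or a
    3'-truncated adapter prefix (at least ``min_overlap`` nt) running to the
    read's end, with a per-occurrence mismatch fraction of at most
    ``max_mismatch_rate``.  When no occurrence is found the read is returned
    unchanged.
    """
    from .formats_io import to_dna

    adapter = to_dna(adapter)
    if len(adapter) < min_overlap:
        raise ValueError(f"adapter must be at least {min_overlap} nt")
    seq = read.sequence
    for start in range(0, len(seq) - min_overlap + 1):
        overlap = min(len(adapter), len(seq) - start)
        if overlap < len(adapter) and start + overlap < len(seq):
            continue  # truncated prefixes only count at the read's very end
        mismatches = sum(
            1 for a, b in zip(seq[start : start + overlap], adapter[:overlap]) if a != b
        )
        if mismatches / overlap <= max_mismatch_rate:
            return QualityRead(
                read.read_id, seq[:start], read.phred[:start], read.count
            )
    return read


def collapse(
    reads: Iterable[QualityRead], min_len: int = DEFAULT_MIN_LEN
) -> list[QualityRead]:
    """Collapse reads into unique sequences of length >= ``min_len``.

    Each output entry carries the summed count of its members and, per base,
    the maximum phred score observed at that position.  Output is sorted by
    descending count and then lexicographically by sequence, and entries are
    renamed ``u<rank>``.
    """
    table: dict[str, tuple[int, list[int]]] = {}
    for read in reads:
        if len(read) < min_len:
            continue
        if read.sequence in table:
            count, phred = table[read.sequence]
            table[read.sequence] = (
                count + read.count,
                [max(a, b) for a, b in zip(phred, read.phred)],
            )
        else:
            table[read.sequence] = (read.count, list(read.phred))
    ordered = sorted(table.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [
        QualityRead(f"u{i + 1}", seq, tuple(phred), count)
        for i, (seq, (count, phred)) in enumerate(ordered)
    ]


def preprocess_reads(
    reads: Iterable[QualityRead],
    adapter: str | None = None,
    min_phred: int = DEFAULT_MIN_PHRED,
    min_len: int = DEFAULT_MIN_LEN,
    max_mismatch_rate: float = DEFAULT_MISMATCH_RATE,
    tail_mode: Literal["trim", "drop"] = "trim",
) -> tuple[list[QualityRead], dict[str, int]]:
    """Full preprocessing of a raw library; returns collapsed unique reads and
    per-stage survival counts.

    ``tail_mode="trim"`` removes low-quality 3' tails base by base;
    ``tail_mode="drop"`` discards any read whose terminal base scores below
    ``min_phred`` outright.
    """
    stats = {"input": 0, "after_quality": 0, "after_adapter": 0, "short_dropped": 0}
    surviving: list[QualityRead] = []
    for read in reads:
        stats["input"] += read.count
        if tail_mode == "drop":
            if read.phred and read.phred[-1] < min_phred:
                continue
        else:
            read = trim_low_quality_tail(read, min_phred)
        if len(read) == 0:
            continue
        stats["after_quality"] += read.count
        if adapter:
            read = strip_adapter(read, adapter, max_mismatch_rate)
        if len(read) == 0:
            continue
        stats["after_adapter"] += read.count
        if len(read) < min_len:
            stats["short_dropped"] += read.count
            continue
        surviving.append(read)
    collapsed = collapse(surviving, min_len=min_len)
    stats["retained"] = sum(r.count for r in collapsed)
    stats["unique"] = len(collapsed)
    return collapsed, stats
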