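"""Readers and writers for every external representation the pipeline touches.

Sequences are stored internally in the DNA alphabet (``T``); ``U`` is accepted
on input and mature-miRNA/report output is rendered back with ``U`` to follow
miRNA convention.  All hairpin coordinates are 1-based and inclusive, matching
the canonical site names (e.g. position 49 of hsa-mir-376a-1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Report value used for a site that is absent from a library.
ABSENT_FDR = "1.00E+00"
#: FDR values below this are printed as 0.00E+00 (numerical underflow).
FDR_UNDERFLOW = 1e-300


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def to_dna(seq: str) -> str:
    """Normalise a nucleotide string to the internal upper-case DNA alphabet."""
    return str(seq).strip().upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a sequence in the RNA alphabet (used for report output)."""
    return str(seq).upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualityRead:
    """A sequenced read with per-base phred scores and library multiplicity.

    ``count`` is the number of identical raw reads this record represents:
    1 for raw FASTQ records and >=1 for collapsed unique reads.
    """

    read_id: str
    sequence: str
    phred: tuple[int, ...]
    count: int = 1

    def __post_init__(self) -> None:
        seq = to_dna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "phred", tuple(int(q) for q in self.phred))
        if len(seq) != len(self.phred):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(seq)} != "
                f"quality length {len(self.phred)}"
            )
        if not set(seq) <= DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise FormatError(f"read {self.read_id!r}: invalid characters {bad}")
        if self.count < 1:
            raise FormatError(f"read {self.read_id!r}: count must be >= 1")
        if any(q < 0 for q in self.phred):
            raise FormatError(f"read {self.read_id!r}: negative phred score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureInterval:
    """One mature-miRNA interval on a hairpin, 1-based inclusive."""

    arm: str  # "5p" or "3p"
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise FormatError(f"mature arm must be 5p or 3p, got {self.arm!r}")
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"invalid mature interval ({self.start}, {self.end})"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA reference sequence with annotated mature arm intervals."""

    hairpin_id: str
    sequence: str
    mature_intervals: tuple[MatureInterval, ...] = ()
    structure: Optional[str] = None

    def __post_init__(self) -> None:
        seq = to_dna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(
            self, "mature_intervals", tuple(self.mature_intervals)
        )
        for iv in self.mature_intervals:
            if iv.end > len(seq):
                raise FormatError(
                    f"hairpin {self.hairpin_id}: mature interval "
                    f"({iv.start}, {iv.end}) outside 1..{len(seq)}"
                )
        ivs = sorted(self.mature_intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise FormatError(
                    f"hairpin {self.hairpin_id}: overlapping mature intervals"
                )
        if self.structure is not None and len(self.structure) != len(seq):
            raise FormatError(
                f"hairpin {self.hairpin_id}: structure length mismatch"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base (DNA) at a 1-based hairpin position."""
        return self.sequence[position - 1]

    def mature_position(self, position: int) -> Optional[tuple[MatureInterval, int]]:
        """The mature interval containing ``position`` and the 1-based offset
        within it, or None when the position is outside every mature arm."""
        for iv in self.mature_intervals:
            if position in iv:
                return iv, position - iv.start + 1
        return None


@dataclass(frozen=True)
class SNPRecord:
    """A known SNP on a hairpin, in hairpin-local coordinates."""

    rs_id: str
    hairpin_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", to_dna(self.ref))
        object.__setattr__(self, "alt", to_dna(self.alt))
        if self.ref == self.alt:
            raise FormatError(f"SNP {self.rs_id}: ref equals alt")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.hairpin_id, self.position, self.ref, self.alt)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    """Stream QualityReads from a Sanger (phred+33) FASTQ file.

    Malformed records raise :class:`FormatError` naming the approximate line.
    """
    path = Path(path)
    n = 0
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ValueError(
                        f"sequence and quality lengths differ for {title!r}"
                    )
                phred = tuple(ord(c) - 33 for c in qual)
                if any(q < 0 or q > 93 for q in phred):
                    raise ValueError(f"quality characters out of range for {title!r}")
                yield QualityRead(title.split()[0], seq, phred, count=1)
                n += 1
        except ValueError as exc:
            raise FormatError(
                f"{path}: malformed FASTQ record near line {4 * n + 1}: {exc}"
            ) from exc


_COUNT_SUFFIX = re.compile(r"^(?P<stem>.*)_(?P<count>\d+)$")


def read_collapsed_fasta(
    path: str | Path,
    default_phred: int = 40,
    strict: bool = True,
) -> Iterator[QualityRead]:
    """Stream pre-collapsed unique reads from a FASTA with count-carrying headers.

    Two header dialects are accepted: a trailing ``_<int>`` on the record id
    (``>u1_350``) or a whitespace-separated numeric second token (``>u2 7``).
    In strict mode a header without a parseable count is an error; otherwise
    the count defaults to 1.  Collapsed inputs carry no qualities, so every
    base receives ``default_phred`` (collapsing happens after quality
    trimming, so retained bases are high quality).
    """
    path = Path(path)
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            tokens = title.split()
            name = tokens[0]
            count = None
            m = _COUNT_SUFFIX.match(name)
            if m:
                count = int(m.group("count"))
            elif len(tokens) > 1 and tokens[1].isdigit():
                count = int(tokens[1])
            if count is None:
                if strict:
                    raise FormatError(
                        f"{path}: header {title!r} carries no read count"
                    )
                count = 1
            if count < 1:
                raise FormatError(f"{path}: header {title!r} has count < 1")
            yield QualityRead(
                name, seq, (default_phred,) * len(seq.strip()), count=count
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA into an ordered mapping id -> DNA sequence."""
    out: dict[str, str] = {}
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            out[title.split()[0]] = to_dna(seq)
    return out


def read_hairpins(
    path: str | Path,
    mature: Optional[Mapping[str, Sequence[MatureInterval]]] = None,
) -> dict[str, Hairpin]:
    """Hairpin FASTA (RNA or DNA) into Hairpin objects, optionally attaching
    mature annotations (validated against each hairpin's length)."""
    out: dict[str, Hairpin] = {}
    for hid, seq in read_fasta(path).items():
        ivs = tuple(mature.get(hid, ())) if mature else ()
        out[hid] = Hairpin(hid, seq, ivs)
    return out


def _looks_like_gff3(path: Path) -> bool:
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            return len(fields) == 9 and "=" in fields[8]
    return False


def _gff_mature_annotations(path: Path) -> dict[str, list[MatureInterval]]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    primaries: dict[str, tuple[str, int, int, str]] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = feat.attributes.get("Name", [feat.id])[0]
        primaries[feat.id] = (name, feat.start, feat.end, feat.strand)
    out: dict[str, list[MatureInterval]] = {}
    for feat in db.features_of_type("miRNA"):
        parents = feat.attributes.get("Derives_from", [])
        if not parents or parents[0] not in primaries:
            raise FormatError(
                f"{path}: miRNA feature {feat.id} lacks a resolvable "
                f"Derives_from primary transcript"
            )
        hp_name, hp_start, hp_end, strand = primaries[parents[0]]
        if strand == "-":
            start = hp_end - feat.end + 1
            end = hp_end - feat.start + 1
        else:
            start = feat.start - hp_start + 1
            end = feat.end - hp_start + 1
        name = feat.attributes.get("Name", [feat.id])[0]
        if name.endswith("-5p"):
            arm = "5p"
        elif name.endswith("-3p"):
            arm = "3p"
        else:
            hp_len = hp_end - hp_start + 1
            arm = "5p" if (start + end) / 2 <= hp_len / 2 else "3p"
        out.setdefault(hp_name, []).append(
            MatureInterval(arm, start, end, name=name)
        )
    return out


def _tsv_mature_annotations(path: Path) -> dict[str, list[MatureInterval]]:
    out: dict[str, list[MatureInterval]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected hairpin/arm/start/end columns"
                )
            hid, arm, start, end = fields[:4]
            name = fields[4] if len(fields) > 4 else ""
            try:
                iv = MatureInterval(arm, int(start), int(end), name=name)
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.setdefault(hid, []).append(iv)
    return out


def read_mature_annotations(
    path: str | Path,
    hairpins: Optional[Mapping[str, Hairpin]] = None,
) -> dict[str, tuple[MatureInterval, ...]]:
    """Mature-miRNA annotations from a miRBase-style GFF3 or a simple TSV
    (columns: hairpin, arm, start, end[, name]), as hairpin-local 1-based
    inclusive intervals keyed by hairpin name.

    When ``hairpins`` is supplied, every interval is validated against the
    corresponding hairpin length; offending records are reported.
    """
    path = Path(path)
    raw = (
        _gff_mature_annotations(path)
        if _looks_like_gff3(path)
        else _tsv_mature_annotations(path)
    )
    if hairpins is not None:
        for hid, ivs in raw.items():
            if hid not in hairpins:
                continue
            hp_len = len(hairpins[hid])
            for iv in ivs:
                if iv.end > hp_len:
                    raise FormatError(
                        f"{path}: mature interval ({iv.start}, {iv.end}) of "
                        f"{hid} exceeds hairpin length {hp_len}"
                    )
    return {hid: tuple(ivs) for hid, ivs in raw.items()}


def _split_table_line(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_snp_table(path: str | Path) -> list[SNPRecord]:
    """Known-SNP TSV (rs_id, hairpin, position, ref, alt); header optional."""
    path = Path(path)
    out: list[SNPRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_table_line(line)
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            if not fields[2].lstrip("-").isdigit():
                continue  # header row
            out.append(
                SNPRecord(fields[0], fields[1], int(fields[2]), fields[3], fields[4])
            )
    return out


def read_editing_table(path: str | Path) -> dict[tuple[str, int, str, str], str]:
    """Known-editing TSV (hairpin, position, ref, alt[, source]); used only to
    annotate the report, never to drive classification."""
    path = Path(path)
    out: dict[tuple[str, int, str, str], str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_table_line(line)
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            if not fields[1].lstrip("-").isdigit():
                continue
            key = (fields[0], int(fields[1]), to_dna(fields[2]), to_dna(fields[3]))
            out[key] = fields[4] if len(fields) > 4 else "known"
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_collapsed_fasta(reads: Iterable[QualityRead], path: str | Path) -> None:
    """Collapsed unique reads as FASTA with trailing ``_<count>`` headers."""
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f">{read.read_id}_{read.count}\n{read.sequence}\n")


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.phred)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def render_ref(ref: str) -> str:
    return "-" if ref == "-" else to_rna(ref).upper()


def render_alt(alt: str) -> str:
    return to_rna(alt).lower()


def format_fdr(fdr: float) -> str:
    return "0.00E+00" if fdr < FDR_UNDERFLOW else f"{fdr:.2E}"


REPORT_FIXED_COLUMNS = (
    "ME_ID",
    "hairpin",
    "position",
    "position_in_mature",
    "ref",
    "alt",
    "category",
)


def write_site_report(sites, libraries: Sequence[str], path: str | Path) -> None:
    """Tab-separated site report: one row per M/E site, with per-library
    MER (weighted edited count, 2 decimals), MEP (percentage, 1 decimal) and
    FDR_P (scientific, 2 significant digits) column triples.

    Sites absent from a library get MER 0.00, MEP 0.0, FDR_P 1.00E+00.
    """
    rows = []
    for site in sites:
        row = {
            "ME_ID": site.me_id,
            "hairpin": site.hairpin_id,
            "position": site.position,
            "position_in_mature": (
                "" if site.position_in_mature is None else site.position_in_mature
            ),
            "ref": render_ref(site.ref),
            "alt": render_alt(site.alt),
            "category": site.category,
        }
        for lib in libraries:
            tally = site.tallies.get(lib)
            if tally is None or tally.n <= 0:
                row[f"{lib}_MER"] = "0.00"
                row[f"{lib}_MEP"] = "0.0"
                row[f"{lib}_FDR_P"] = ABSENT_FDR
            else:
                row[f"{lib}_MER"] = f"{tally.mer:.2f}"
                row[f"{lib}_MEP"] = f"{100.0 * tally.p_o:.1f}"
                row[f"{lib}_FDR_P"] = format_fdr(tally.fdr_p)
        rows.append(row)
    columns = list(REPORT_FIXED_COLUMNS) + [
        f"{lib}_{col}" for lib in libraries for col in ("MER", "MEP", "FDR_P")
    ]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)


def read_site_report(path: str | Path) -> pd.DataFrame:
    """Parse a site report back into a DataFrame (all columns as strings)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
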