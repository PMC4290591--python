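"""Fully-specified synthetic small-RNA sequencing data with planted ground
truth, so the whole pipeline is testable without any download.

The generator emulates the structure of a small-RNA HTS experiment: a set of
pre-miRNA hairpins embedded in a genome, four sequencing libraries of reads
drawn from the mature arms with 5'/3' length jitter, phred-dependent
sequencing error, a 3' sequencing adapter, and planted events — internal
substitutions (editing/SNPs) at controlled per-site rates, 3' non-templated
single-nucleotide additions, and a family of near-identical loci whose shared
reads exercise the cross-mapping machinery (a "pseudo" construct).  Every
output is a plain-text file and is byte-identical for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    Hairpin,
    MatureInterval,
    QualityRead,
    to_dna,
    to_rna,
    write_fastq,
)
from .site_calling import name_site, phred_to_error

NUCLEOTIDES = "ACGT"

#: Mature 5p arm used for every synthetic hairpin (1-based inclusive); reads
#: are drawn from this arm.  The 3p arm is annotated relative to the hairpin
#: 3' end.
ARM5 = (10, 31)
ARM3_OFFSETS = (30, 9)  # (len - 30, len - 9)

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedEvent:
    """One planted mutation/editing event on a hairpin.

    ``kind`` is the category the pipeline is expected to assign (3' kinds are
    simulated as non-templated additions after the mature 3' end, everything
    else as internal substitutions).  ``ref`` is forced into the hairpin
    sequence at ``position``; when omitted a base differing from ``alt`` is
    chosen.  Events with ``expect_significant=False`` document deliberately
    sub-threshold rates.
    """

    hairpin: str
    position: int
    alt: str
    rate: float
    kind: str
    ref: Optional[str] = None
    expect_significant: bool = True

    @property
    def is_tail(self) -> bool:
        return self.kind.startswith("3'")


@dataclass(frozen=True)
class PseudoFamily:
    """A family of identical hairpin loci generating shared low-weight reads.

    All ``n_copies`` hairpins have the same sequence and each is present once
    in the genome, so every read from the family maps to every copy and
    carries weight ``1 / n_copies`` (< 0.05 for 21+ copies).  The planted
    substitution therefore produces an apparently significant site at every
    copy that is supported exclusively by sub-threshold-weight reads — the
    construct the Pseudo category exists for.
    """

    n_copies: int = 21
    coverage: int = 1200
    position: int = 20
    ref: str = "A"
    alt: str = "G"
    rate: float = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Complete description of a synthetic experiment."""

    seed: int
    n_hairpins: int = 8
    hairpin_len: tuple[int, int] = (76, 84)
    libraries: tuple[str, ...] = ("N_no_TAI", "T_no_TAI", "N_with_TAI", "T_with_TAI")
    coverage: int = 200
    phred: int = 40
    read_length: int = 36
    adapter: str = DEFAULT_ADAPTER
    events: tuple[PlantedEvent, ...] = ()
    pseudo: Optional[PseudoFamily] = None
    duplicated_locus_copies: tuple[tuple[str, int], ...] = ()
    pad_len: int = 120

    def validate(self) -> None:
        problems: list[str] = []
        lo, hi = self.hairpin_len
        if not 62 <= lo <= hi:
            problems.append(f"hairpin_len: range ({lo}, {hi}) must satisfy 62 <= lo <= hi")
        if self.coverage < 1:
            problems.append("coverage: must be >= 1")
        if self.phred < 0:
            problems.append("phred: must be >= 0")
        if len(self.adapter) < 5:
            problems.append("adapter: must be at least 5 nt")
        names = {f"syn-mir-{i + 1:02d}" for i in range(self.n_hairpins)}
        for ev in self.events:
            if ev.hairpin not in names:
                problems.append(f"events: unknown hairpin {ev.hairpin!r}")
            if not 0.0 <= ev.rate <= 1.0:
                problems.append(f"events: rate {ev.rate} outside [0, 1]")
            if to_dna(ev.alt) not in NUCLEOTIDES:
                problems.append(f"events: invalid alt {ev.alt!r}")
            limit = lo + 1 if ev.is_tail else lo
            if not 1 <= ev.position <= limit:
                problems.append(
                    f"events: position {ev.position} outside 1..{limit} "
                    f"({ev.hairpin})"
                )
            if ev.is_tail and ev.position != ARM5[1] + 1:
                problems.append(
                    f"events: 3' addition must sit at position {ARM5[1] + 1} "
                    f"(just past the mature 3' end), got {ev.position}"
                )
        if self.pseudo is not None:
            if self.pseudo.n_copies < 2:
                problems.append("pseudo: n_copies must be >= 2")
            if not 0.0 <= self.pseudo.rate <= 1.0:
                problems.append("pseudo: rate outside [0, 1]")
        if problems:
            raise SimConfigError("; ".join(problems))


def default_experiment(seed: int) -> SimConfig:
    """The standard simulated experiment used throughout testing.

    Four libraries at 200x mature coverage and phred 40, with one planted
    event per hairpin: an A-to-I edit at 20%, a C-to-U edit at 10%, 3'-A and
    3'-U additions at 30%, a homozygous SNP (rate 1.0), a deliberately
    sub-threshold edit at 2%, two clean hairpins, and a 21-copy pseudo
    family edited at 30%.
    """
    events = (
        PlantedEvent("syn-mir-01", 20, "G", 0.20, "A-to-I", ref="A"),
        PlantedEvent("syn-mir-02", 22, "T", 0.10, "C-to-U", ref="C"),
        PlantedEvent("syn-mir-03", ARM5[1] + 1, "A", 0.30, "3'-A", ref="C"),
        PlantedEvent("syn-mir-04", ARM5[1] + 1, "T", 0.30, "3'-U", ref="G"),
        PlantedEvent("syn-mir-05", 18, "A", 1.00, "SNP", ref="G"),
        PlantedEvent(
            "syn-mir-06", 24, "G", 0.02, "A-to-I", ref="A", expect_significant=False
        ),
    )
    return SimConfig(seed=seed, events=events, pseudo=PseudoFamily())


@dataclass
class SimOutput:
    """Paths and ground truth of a simulated experiment."""

    hairpin_fasta: Path
    mature_tsv: Path
    genome_fasta: Path
    snp_tsv: Path
    truth_tsv: Path
    fastqs: dict[str, Path]
    truth: pd.DataFrame
    hairpins: dict[str, Hairpin]


class Simulator:
    """Deterministic builder for one synthetic experiment."""

    def __init__(self, config: SimConfig) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.hairpins: dict[str, Hairpin] = {}
        self._build_hairpins(rng)
        self._build_genome(rng)
        self.truth = self._build_truth()

    # -- references --------------------------------------------------------

    def _random_seq(self, rng: np.random.Generator, length: int) -> list[str]:
        return [NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length)]

    def _mature(self, length: int) -> tuple[MatureInterval, MatureInterval]:
        return (
            MatureInterval("5p", ARM5[0], ARM5[1]),
            MatureInterval("3p", length - ARM3_OFFSETS[0], length - ARM3_OFFSETS[1]),
        )

    def _build_hairpins(self, rng: np.random.Generator) -> None:
        cfg = self.config
        lo, hi = cfg.hairpin_len
        events_by_hp: dict[str, list[PlantedEvent]] = {}
        resolved: list[PlantedEvent] = []
        for i in range(cfg.n_hairpins):
            name = f"syn-mir-{i + 1:02d}"
            length = int(rng.integers(lo, hi + 1))
            seq = self._random_seq(rng, length)
            for ev in cfg.events:
                if ev.hairpin != name:
                    continue
                alt = to_dna(ev.alt)
                ref = to_dna(ev.ref) if ev.ref else None
                if ref is None or ref == alt:
                    choices = [b for b in NUCLEOTIDES if b != alt]
                    ref = choices[int(rng.integers(0, len(choices)))]
                seq[ev.position - 1] = ref
                ev = replace(ev, ref=ref, alt=alt)
                events_by_hp.setdefault(name, []).append(ev)
                resolved.append(ev)
            self.hairpins[name] = Hairpin(name, "".join(seq), self._mature(length))
        self.events_by_hp = events_by_hp
        self.resolved_events = resolved

        if cfg.pseudo is not None:
            fam = cfg.pseudo
            length = 80
            seq = self._random_seq(rng, length)
            alt = to_dna(fam.alt)
            ref = to_dna(fam.ref)
            if ref == alt:
                ref = next(b for b in NUCLEOTIDES if b != alt)
            seq[fam.position - 1] = ref
            fam_seq = "".join(seq)
            self.family_ids = tuple(
                f"syn-mir-fam-{i + 1:02d}" for i in range(fam.n_copies)
            )
            for fid in self.family_ids:
                self.hairpins[fid] = Hairpin(fid, fam_seq, self._mature(length))
            self.family_event = replace(
                PlantedEvent("", fam.position, alt, fam.rate, "Pseudo", ref=ref),
                hairpin=self.family_ids[0],
            )
        else:
            self.family_ids = ()
            self.family_event = None

    def _build_genome(self, rng: np.random.Generator) -> None:
        cfg = self.config
        parts: list[str] = ["".join(self._random_seq(rng, cfg.pad_len))]
        for hid in self.hairpins:  # insertion order: numbered, then family
            parts.append(self.hairpins[hid].sequence)
            parts.append("".join(self._random_seq(rng, cfg.pad_len)))
        for hid, copies in cfg.duplicated_locus_copies:
            for _ in range(copies):
                parts.append(self.hairpins[hid].sequence)
                parts.append("".join(self._random_seq(rng, cfg.pad_len)))
        self.genome = {"chrS": "".join(parts)}

    def _build_truth(self) -> pd.DataFrame:
        rows = []
        for ev in self.resolved_events:
            rows.append(
                {
                    "me_id": name_site(ev.hairpin, ev.position, ev.ref, ev.alt),
                    "hairpin": ev.hairpin,
                    "position": ev.position,
                    "ref": ev.ref,
                    "alt": ev.alt,
                    "category": ev.kind,
                    "rate": ev.rate,
                    "expect_significant": ev.expect_significant,
                }
            )
        if self.family_event is not None:
            ev = self.family_event
            for fid in self.family_ids:
                rows.append(
                    {
                        "me_id": name_site(fid, ev.position, ev.ref, ev.alt),
                        "hairpin": fid,
                        "position": ev.position,
                        "ref": ev.ref,
                        "alt": ev.alt,
                        "category": "Pseudo",
                        "rate": ev.rate,
                        "expect_significant": True,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "me_id", "hairpin", "position", "ref", "alt",
                "category", "rate", "expect_significant",
            ],
        )

    # -- reads -------------------------------------------------------------

    def _draw_read(
        self,
        rng: np.random.Generator,
        hairpin: Hairpin,
        events: Sequence[PlantedEvent],
        read_id: str,
    ) -> QualityRead:
        cfg = self.config
        has_tail_event = any(ev.is_tail for ev in events)
        d5 = int(rng.choice((0, 1, 2), p=(0.8, 0.15, 0.05)))
        # hairpins carrying a 3' addition keep fixed templated 3' ends so the
        # addition is the only source of variation past the mature end
        d3 = 0 if has_tail_event else int(rng.choice((0, 1, -1), p=(0.7, 0.15, 0.15)))
        start, end = ARM5[0] + d5, ARM5[1] + d3
        bases = list(hairpin.sequence[start - 1 : end])
        for ev in events:
            if ev.is_tail:
                if rng.random() < ev.rate:
                    bases.append(ev.alt)
            elif start <= ev.position <= end:
                if rng.random() < ev.rate:
                    bases[ev.position - start] = ev.alt
        bases.extend(cfg.adapter)
        bases = bases[: cfg.read_length]
        error = phred_to_error(cfg.phred)
        for k in range(len(bases)):
            if rng.random() < error:
                others = [b for b in NUCLEOTIDES if b != bases[k]]
                bases[k] = others[int(rng.integers(0, 3))]
        return QualityRead(read_id, "".join(bases), (cfg.phred,) * len(bases))

    def library_reads(self, library: str) -> list[QualityRead]:
        """All raw reads of one library, reproducible from the master seed.

        Read ids encode the true origin locus: ``{library}:{hairpin}:{index}``.
        """
        cfg = self.config
        lib_index = cfg.libraries.index(library)
        rng = np.random.default_rng([cfg.seed, 1000 + lib_index])
        reads: list[QualityRead] = []
        for i in range(cfg.n_hairpins):
            hid = f"syn-mir-{i + 1:02d}"
            events = self.events_by_hp.get(hid, [])
            for j in range(cfg.coverage):
                reads.append(
                    self._draw_read(rng, self.hairpins[hid], events, f"{library}:{hid}:{j:05d}")
                )
        if self.family_event is not None:
            origin = self.family_ids[0]
            for j in range(self.config.pseudo.coverage):
                reads.append(
                    self._draw_read(
                        rng,
                        self.hairpins[origin],
                        [self.family_event],
                        f"{library}:{origin}:{j:05d}",
                    )
                )
        return reads

    # -- files -------------------------------------------------------------

    def write(self, out_dir: str | Path, libraries: Optional[Sequence[str]] = None) -> SimOutput:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        hairpin_fasta = out / "hairpins.fa"
        with open(hairpin_fasta, "w") as fh:
            for hid, hp in self.hairpins.items():
                fh.write(f">{hid}\n{to_rna(hp.sequence)}\n")
        mature_tsv = out / "mature.tsv"
        with open(mature_tsv, "w") as fh:
            fh.write("# hairpin\tarm\tstart\tend\n")
            for hid, hp in self.hairpins.items():
                for iv in hp.mature_intervals:
                    fh.write(f"{hid}\t{iv.arm}\t{iv.start}\t{iv.end}\n")
        genome_fasta = out / "genome.fa"
        with open(genome_fasta, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")
        snp_tsv = out / "snps.tsv"
        with open(snp_tsv, "w") as fh:
            fh.write("# rs_id\thairpin\tposition\tref\talt\n")
            n = 0
            for ev in self.resolved_events:
                if ev.kind == "SNP":
                    n += 1
                    fh.write(
                        f"rsSYN{n}\t{ev.hairpin}\t{ev.position}\t{ev.ref}\t{ev.alt}\n"
                    )
        truth_tsv = out / "truth.tsv"
        self.truth.to_csv(truth_tsv, sep="\t", index=False)
        fastqs: dict[str, Path] = {}
        for lib in libraries if libraries is not None else cfg.libraries:
            path = out / f"{lib}.fastq"
            write_fastq(self.library_reads(lib), path)
            fastqs[lib] = path
        return SimOutput(
            hairpin_fasta=hairpin_fasta,
            mature_tsv=mature_tsv,
            genome_fasta=genome_fasta,
            snp_tsv=snp_tsv,
            truth_tsv=truth_tsv,
            fastqs=fastqs,
            truth=self.truth,
            hairpins=self.hairpins,
        )


def simulate_library(
    config: SimConfig, out_dir: str | Path, library: Optional[str] = None
) -> SimOutput:
    """Generate the shared references plus a single library's FASTQ."""
    lib = library or config.libraries[0]
    return Simulator(config).write(out_dir, libraries=[lib])


def simulate_experiment(config: SimConfig, out_dir: str | Path) -> SimOutput:
    """Generate references, ground truth and every library of the experiment."""
    return Simulator(config).write(out_dir)


def make_cross_mapping_fixture(
    copies: int,
    unique_counts: Optional[Sequence[int]] = None,
    shared_count: int = 4,
    read_len: int = 24,
    seed: int = 0,
):
    """A genome with ``copies`` near-identical loci and reads with known
    per-locus origin counts, for exact weight-recovery assertions.

    Each locus is a shared core (to which one shared read maps exactly) glued
    to a locus-specific flank; the junction-spanning unique reads pin down
    each locus's own expression.  Returns ``(genome, reads)`` where the
    shared read is named ``shared`` and unique reads ``unique<i>``.
    """
    if copies < 2:
        raise ValueError("need at least 2 locus copies")
    rng = np.random.default_rng(seed)
    core = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=read_len))
    half = read_len // 2
    parts = ["".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=60))]
    flanks = []
    for _ in range(copies):
        flank = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=read_len))
        flanks.append(flank)
        parts.append(core + flank)
        parts.append("".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=60)))
    genome = {"chrX": "".join(parts)}
    reads = [
        QualityRead("shared", core, (40,) * len(core), count=shared_count)
    ]
    if unique_counts is not None:
        if len(unique_counts) != copies:
            raise ValueError("unique_counts must have one entry per copy")
        for i, count in enumerate(unique_counts):
            if count <= 0:
                continue
            seq = core[-half:] + flanks[i][:half]
            reads.append(
                QualityRead(f"unique{i + 1}", seq, (40,) * len(seq), count=count)
            )
    return genome, reads
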