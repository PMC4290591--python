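"""End-to-end orchestration: preprocess -> hairpin alignment -> genome-locus
enumeration -> cross-mapping weights -> site calling -> per-library merge and
reporting.

Each read's evidence at a hairpin is weighted by how confidently the read can
be attributed to that locus.  Reads found in the genome get the iterative
cross-mapping weight of the genomic locus that overlaps the hairpin; reads
aligning to a hairpin but absent from the genome ("missed reads", typically
the edited reads themselves) are divided evenly across their best-scoring
hairpin loci; reads occurring at more than ``max_loci`` genomic loci are
discarded outright.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import crossmap, formats_io, hairpin_align, preprocess, site_calling
from .crossmap import Locus
from .formats_io import Hairpin, QualityRead
from .hairpin_align import (
    DELETION,
    DISCARDED,
    INSERTION,
    MATCH,
    MISMATCH,
    AlignmentHit,
    KmerIndex,
    ScoringScheme,
)
from .site_calling import MESite, PileupRead, PositionTally

logger = logging.getLogger("miredit")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run.

    Every calling threshold is a named key with its standard default: reads
    of >= 18 nt, phred threshold 20, >= 10 supporting reads, >= 5% M/E
    fraction, corrected p < 0.05, > 100 genomic loci discarded, cross-mapping
    weight < 0.05 for pseudo detection.
    """

    libraries: dict[str, str] = field(default_factory=dict)
    hairpin_fasta: str = ""
    mature: str = ""
    genome_fasta: Optional[str] = None
    snp_table: Optional[str] = None
    editing_table: Optional[str] = None
    out_dir: Optional[str] = None
    adapter: Optional[str] = None
    min_phred: int = 20
    min_len: int = 18
    tail_mode: str = "trim"
    adapter_mismatch_rate: float = 0.1
    min_align_score: int = 50
    seed_k: int = 8
    max_loci: int = 100
    min_reads: float = 10.0
    min_fraction: float = 0.05
    alpha: float = 0.05
    pseudo_weight: float = 0.05
    tail_window: int = 6
    pe_floor: float = 0.01
    collapsed_phred: int = 40
    match_reward: int = 4
    mismatch_penalty: int = -3
    gap_open: int = -4
    gap_extend: int = -2

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            self.match_reward, self.mismatch_penalty, self.gap_open, self.gap_extend
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclass_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.libraries:
            raise FileNotFoundError("config names no sequencing libraries")
        missing = [
            str(p)
            for p in [
                self.hairpin_fasta,
                self.mature,
                self.genome_fasta,
                self.snp_table,
                self.editing_table,
                *self.libraries.values(),
            ]
            if p and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class LibraryResult:
    """Intermediate products of one library's pass through the pipeline."""

    library: str
    collapsed: list[QualityRead]
    alignments: dict[str, dict[str, AlignmentHit]]  # read_id -> hairpin -> hit
    hairpin_weights: dict[str, dict[str, float]]  # read_id -> hairpin -> weight
    locus_weights: dict[str, dict[Locus, float]]
    discarded: set[str]
    tallies: list[PositionTally]
    significant: list[tuple[PositionTally, str]]
    stats: dict[str, int]


@dataclass
class PipelineResult:
    sites: list[MESite]
    n_common: int
    libraries: list[str]
    per_library: dict[str, LibraryResult]
    category_table: pd.DataFrame
    stats: dict[str, dict[str, int]]
    report_path: Optional[Path] = None


# ---------------------------------------------------------------------------
# reference bookkeeping
# ---------------------------------------------------------------------------


def load_references(config: PipelineConfig):
    mature = formats_io.read_mature_annotations(config.mature)
    hairpins = formats_io.read_hairpins(config.hairpin_fasta, mature=mature)
    genome = (
        formats_io.read_fasta(config.genome_fasta) if config.genome_fasta else {}
    )
    snps = (
        formats_io.read_snp_table(config.snp_table) if config.snp_table else []
    )
    editing = (
        formats_io.read_editing_table(config.editing_table)
        if config.editing_table
        else {}
    )
    return hairpins, genome, snps, editing


def hairpin_footprints(
    hairpins: Mapping[str, Hairpin], genome: Mapping[str, str]
) -> dict[str, Locus]:
    """Genomic footprint of each hairpin, by exact sequence occurrence.

    Hairpins sharing one sequence (duplicated-family loci) are paired with
    genome occurrences in sorted order, giving a consistent one-to-one
    assignment; occurrences beyond the number of hairpin ids remain plain
    genomic loci.
    """
    by_seq: dict[str, list[str]] = {}
    for hid in sorted(hairpins):
        by_seq.setdefault(hairpins[hid].sequence, []).append(hid)
    footprints: dict[str, Locus] = {}
    for seq, hids in by_seq.items():
        occurrences: list[Locus] = []
        for chrom in sorted(genome):
            gseq = genome[chrom]
            for query, strand in ((seq, "+"), (formats_io.revcomp(seq), "-")):
                if strand == "-" and query == seq:
                    continue
                start = gseq.find(query)
                while start != -1:
                    occurrences.append(
                        Locus(chrom, start + 1, start + len(seq), strand)
                    )
                    start = gseq.find(query, start + 1)
        occurrences.sort()
        for hid, locus in zip(hids, occurrences):
            footprints[hid] = locus
    return footprints


def _locus_within(inner: Locus, outer: Locus) -> bool:
    return (
        inner.chrom == outer.chrom
        and inner.start >= outer.start
        and inner.end <= outer.end
    )


# ---------------------------------------------------------------------------
# per-library stages
# ---------------------------------------------------------------------------


def _load_reads(path: str, config: PipelineConfig):
    if str(path).endswith((".fa", ".fasta", ".fa.txt")):
        return list(
            formats_io.read_collapsed_fasta(
                path, default_phred=config.collapsed_phred
            )
        )
    return list(formats_io.read_fastq(path))


def align_library(
    collapsed: Sequence[QualityRead],
    hairpins: Mapping[str, Hairpin],
    config: PipelineConfig,
    index: Optional[KmerIndex] = None,
) -> dict[str, dict[str, AlignmentHit]]:
    """Best local alignment of every unique read against its candidate
    hairpins (k-mer seeded), keeping hits scoring >= ``min_align_score``."""
    if index is None:
        index = KmerIndex(hairpins, k=config.seed_k)
    scheme = config.scheme
    out: dict[str, dict[str, AlignmentHit]] = {}
    for read in collapsed:
        hits: dict[str, AlignmentHit] = {}
        for hid in index.candidate_ids(read.sequence):
            hit = hairpin_align.local_align(
                read.sequence,
                hairpins[hid].sequence,
                scheme,
                min_score=config.min_align_score,
                read_id=read.read_id,
                target_id=hid,
            )
            if hit is not None:
                hits[hid] = hit
        if hits:
            out[read.read_id] = hits
    return out


def weight_library(
    collapsed: Sequence[QualityRead],
    alignments: Mapping[str, Mapping[str, AlignmentHit]],
    genome: Mapping[str, str],
    footprints: Mapping[str, Locus],
    config: PipelineConfig,
) -> tuple[dict[str, dict[str, float]], dict[str, dict[Locus, float]], set[str]]:
    """Cross-mapping weights of every aligned read at every hairpin.

    Returns (hairpin weights, genomic locus weights, discarded read ids).
    """
    reads_by_id = {r.read_id: r for r in collapsed}
    genome_loci: dict[str, list[Locus]] = {}
    discarded: set[str] = set()
    for rid in sorted(alignments):
        result = hairpin_align.map_to_genome(
            reads_by_id[rid].sequence, genome, max_loci=config.max_loci, read_id=rid
        )
        if result is DISCARDED:
            discarded.add(rid)
        else:
            loci = [
                Locus(h.target_id, h.target_start, h.target_end, h.strand)
                for h in result
            ]
            if loci:
                genome_loci[rid] = loci

    locus_weights = crossmap.assign_weights(
        {rid: genome_loci[rid] for rid in genome_loci},
        {rid: float(reads_by_id[rid].count) for rid in genome_loci},
    )

    hairpin_weights: dict[str, dict[str, float]] = {}
    for rid in sorted(alignments):
        if rid in discarded:
            continue
        hits = alignments[rid]
        if rid in locus_weights:
            per_hp: dict[str, float] = {}
            for hid in hits:
                fp = footprints.get(hid)
                if fp is None:
                    continue
                w = sum(
                    wt
                    for locus, wt in locus_weights[rid].items()
                    if _locus_within(locus, fp)
                )
                if w > 0:
                    per_hp[hid] = w
            if per_hp:
                hairpin_weights[rid] = per_hp
        else:
            # missed read: aligned to hairpins but absent from the genome
            resolved = crossmap.resolve_missed_read(
                [(hid, hits[hid].score) for hid in sorted(hits)],
                genome_hits=(),
                max_loci=config.max_loci,
            )
            if resolved:
                hairpin_weights[rid] = dict(resolved)
    return hairpin_weights, locus_weights, discarded


def tally_library(
    library: str,
    collapsed: Sequence[QualityRead],
    alignments: Mapping[str, Mapping[str, AlignmentHit]],
    hairpin_weights: Mapping[str, Mapping[str, float]],
    hairpins: Mapping[str, Hairpin],
    config: PipelineConfig,
) -> tuple[list[PositionTally], dict[str, list[PileupRead]]]:
    """Weighted pileups for every hairpin with aligned reads."""
    reads_by_id = {r.read_id: r for r in collapsed}
    placements: dict[str, list[PileupRead]] = {}
    for rid, per_hp in hairpin_weights.items():
        for hid, w in per_hp.items():
            if w <= 0 or hid not in alignments.get(rid, {}):
                continue
            placements.setdefault(hid, []).append(
                PileupRead(reads_by_id[rid], alignments[rid][hid], w)
            )
    tallies: list[PositionTally] = []
    for hid in sorted(placements):
        tallies.extend(
            site_calling.pileup(
                hairpins[hid],
                placements[hid],
                min_phred=config.min_phred,
                pe_floor=config.pe_floor,
                tail_window=config.tail_window,
                library=library,
            )
        )
    return tallies, placements


def call_library(
    library: str,
    tallies: list[PositionTally],
    placements: Mapping[str, Sequence[PileupRead]],
    hairpins: Mapping[str, Hairpin],
    snps,
    config: PipelineConfig,
) -> list[tuple[PositionTally, str]]:
    """Significant sites of one library with their categories.

    Pseudo detection recomputes each candidate site's tally from the pileup
    restricted to reads with cross-mapping weight >= ``pseudo_weight``; a
    site that no longer satisfies the calling criteria is Pseudo.
    """
    significant = site_calling.call_significant(
        tallies,
        min_reads=config.min_reads,
        min_fraction=config.min_fraction,
        alpha=config.alpha,
    )
    snp_keys = {rec.key for rec in snps}
    filtered_cache: dict[str, Optional[dict[tuple, PositionTally]]] = {}
    out: list[tuple[PositionTally, str]] = []
    for tally in significant:
        hid = tally.hairpin_id
        if hid not in filtered_cache:
            full = placements.get(hid, ())
            kept = [p for p in full if p.weight >= config.pseudo_weight]
            if len(kept) == len(full):
                filtered_cache[hid] = None  # no low-weight reads to remove
            else:
                filtered_cache[hid] = {
                    t.key: t
                    for t in site_calling.pileup(
                        hairpins[hid],
                        kept,
                        min_phred=config.min_phred,
                        pe_floor=config.pe_floor,
                        tail_window=config.tail_window,
                        library=library,
                    )
                }
        cache = filtered_cache[hid]
        category = site_calling.classify(
            tally,
            hairpins[hid],
            snp_table=snp_keys,
            filtered_tally=None if cache is None else cache.get(tally.key),
            check_pseudo=cache is not None,
            min_reads=config.min_reads,
            min_fraction=config.min_fraction,
            alpha=config.alpha,
            tail_window=config.tail_window,
        )
        out.append((tally, category))
    return out


# ---------------------------------------------------------------------------
# intermediates
# ---------------------------------------------------------------------------


def hit_to_cigar(hit: AlignmentHit) -> str:
    ops = []
    for col in hit.columns:
        op = {MATCH: "=", MISMATCH: "X", INSERTION: "I", DELETION: "D"}[col.kind]
        if ops and ops[-1][1] == op:
            ops[-1][0] += 1
        else:
            ops.append([1, op])
    return "".join(f"{n}{op}" for n, op in ops)


def cigar_to_hit(
    cigar: str,
    read_seq: str,
    target_seq: str,
    target_start: int,
    read_start: int,
    read_id: str,
    target_id: str,
    scheme: ScoringScheme,
) -> AlignmentHit:
    """Rebuild an AlignmentHit from its serialised form."""
    import re

    columns = []
    t, r = target_start, read_start
    for n, op in re.findall(r"(\d+)([=XID])", cigar):
        for _ in range(int(n)):
            if op in "=X":
                columns.append(
                    hairpin_align.AlignmentColumn(
                        t, r, target_seq[t - 1], read_seq[r - 1],
                        MATCH if op == "=" else MISMATCH,
                    )
                )
                t, r = t + 1, r + 1
            elif op == "I":
                columns.append(
                    hairpin_align.AlignmentColumn(None, r, "-", read_seq[r - 1], INSERTION)
                )
                r += 1
            else:
                columns.append(
                    hairpin_align.AlignmentColumn(t, None, target_seq[t - 1], "-", DELETION)
                )
                t += 1
    columns = tuple(columns)
    return AlignmentHit(
        read_id=read_id,
        target_id=target_id,
        target_start=target_start,
        target_end=t - 1,
        strand="+",
        score=hairpin_align.score_columns(columns, scheme),
        columns=columns,
    )


def alignments_table(
    collapsed: Sequence[QualityRead],
    alignments: Mapping[str, Mapping[str, AlignmentHit]],
) -> pd.DataFrame:
    reads_by_id = {r.read_id: r for r in collapsed}
    rows = []
    for rid in sorted(alignments):
        for hid, hit in sorted(alignments[rid].items()):
            rows.append(
                {
                    "read_id": rid,
                    "count": reads_by_id[rid].count,
                    "sequence": reads_by_id[rid].sequence,
                    "hairpin": hid,
                    "target_start": hit.target_start,
                    "target_end": hit.target_end,
                    "read_start": hit.read_span[0],
                    "score": hit.score,
                    "cigar": hit_to_cigar(hit),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "count", "sequence", "hairpin",
            "target_start", "target_end", "read_start", "score", "cigar",
        ],
    )


def tallies_table(tallies: Sequence[PositionTally]) -> pd.DataFrame:
    rows = [
        {
            "library": t.library,
            "hairpin": t.hairpin_id,
            "position": t.position,
            "ref": t.ref,
            "alt": t.alt,
            "n": round(t.n, 4),
            "mer": round(t.mer, 4),
            "p_o": round(t.p_o, 6),
            "p_e": round(t.p_e, 6),
            "z": round(t.z, 4),
            "p_value": t.p_value,
            "fdr_p": t.fdr_p,
        }
        for t in tallies
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "library", "hairpin", "position", "ref", "alt",
            "n", "mer", "p_o", "p_e", "z", "p_value", "fdr_p",
        ],
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def process_library(
    library: str,
    reads_path: str,
    hairpins: Mapping[str, Hairpin],
    genome: Mapping[str, str],
    footprints: Mapping[str, Locus],
    snps,
    config: PipelineConfig,
    index: Optional[KmerIndex] = None,
) -> LibraryResult:
    raw = _load_reads(reads_path, config)
    collapsed, stats = preprocess.preprocess_reads(
        raw,
        adapter=config.adapter,
        min_phred=config.min_phred,
        min_len=config.min_len,
        max_mismatch_rate=config.adapter_mismatch_rate,
        tail_mode=config.tail_mode,  # type: ignore[arg-type]
    )
    if not collapsed:
        logger.warning("library %s: no reads survive preprocessing", library)
    alignments = align_library(collapsed, hairpins, config, index=index)
    hairpin_weights, locus_weights, discarded = weight_library(
        collapsed, alignments, genome, footprints, config
    )
    tallies, placements = tally_library(
        library, collapsed, alignments, hairpin_weights, hairpins, config
    )
    significant = call_library(library, tallies, placements, hairpins, snps, config)
    stats.update(
        {
            "aligned_unique": len(alignments),
            "discarded_multi": len(discarded),
            "candidate_tallies": len(tallies),
            "significant_sites": len(significant),
        }
    )
    logger.info(
        "library %s: %d unique reads, %d aligned, %d discarded (> %d loci), "
        "%d candidate tallies, %d significant sites",
        library, len(collapsed), len(alignments), len(discarded),
        config.max_loci, len(tallies), len(significant),
    )
    return LibraryResult(
        library=library,
        collapsed=collapsed,
        alignments=alignments,
        hairpin_weights=hairpin_weights,
        locus_weights=locus_weights,
        discarded=discarded,
        tallies=tallies,
        significant=significant,
        stats=stats,
    )


def run_pipeline(
    config: PipelineConfig, out_dir: Optional[str | Path] = None
) -> PipelineResult:
    """Run every stage over every configured library and merge the results.

    When ``out_dir`` (or ``config.out_dir``) is given, every stage writes its
    intermediate TSV there alongside the final report, category summary and
    stage-survival log.
    """
    config.validate()
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    hairpins, genome, snps, editing = load_references(config)
    footprints = hairpin_footprints(hairpins, genome)
    index = KmerIndex(hairpins, k=config.seed_k)

    per_library: dict[str, LibraryResult] = {}
    for library in config.libraries:
        result = process_library(
            library, config.libraries[library], hairpins, genome, footprints,
            snps, config, index=index,
        )
        per_library[library] = result
        if out is not None:
            formats_io.write_collapsed_fasta(
                result.collapsed, out / f"{library}.collapsed.fa"
            )
            alignments_table(result.collapsed, result.alignments).to_csv(
                out / f"{library}.alignments.tsv", sep="\t", index=False
            )
            crossmap.weights_table(result.locus_weights).to_csv(
                out / f"{library}.weights.tsv", sep="\t", index=False
            )
            tallies_table(result.tallies).to_csv(
                out / f"{library}.tallies.tsv", sep="\t", index=False
            )
            tallies_table([t for t, _ in result.significant]).assign(
                category=[c for _, c in result.significant]
            ).to_csv(out / f"{library}.sites.tsv", sep="\t", index=False)

    libraries = list(config.libraries)
    sites, n_common = site_calling.merge_libraries(
        {lib: per_library[lib].significant for lib in libraries},
        {lib: per_library[lib].tallies for lib in libraries},
        hairpins,
        editing_table=editing,
    )
    category_table = site_calling.category_counts(sites, libraries)
    stats = {lib: per_library[lib].stats for lib in libraries}
    report_path = None
    if out is not None:
        report_path = out / "report.tsv"
        formats_io.write_site_report(sites, libraries, report_path)
        category_table.to_csv(out / "categories.tsv", sep="\t", index=False)
        with open(out / "pipeline_stats.json", "w") as fh:
            json.dump(
                {"n_sites": len(sites), "n_common": n_common, "libraries": stats},
                fh,
                indent=2,
            )
    logger.info(
        "merged %d M/E sites (%d significant in all %d libraries)",
        len(sites), n_common, len(libraries),
    )
    return PipelineResult(
        sites=sites,
        n_common=n_common,
        libraries=libraries,
        per_library=per_library,
        category_table=category_table,
        stats=stats,
        report_path=report_path,
    )
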