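from __future__ import annotations

import textwrap

import pytest

from miredit import formats_io as fio
from miredit.formats_io import (
    FormatError,
    Hairpin,
    MatureInterval,
    QualityRead,
    SNPRecord,
)
from miredit.site_calling import MESite, PositionTally


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


class TestFastq:
    def test_phred33_decoding_and_unit_count(self, tmp_path):
        path = write(tmp_path, "a.fastq", "@r1\nACGT\n+\nIIII\n")
        (read,) = list(fio.read_fastq(path))
        assert read.phred == (40, 40, 40, 40)
        assert read.count == 1
        assert read.sequence == "ACGT"

    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = write(tmp_path, "e.fastq", "")
        assert list(fio.read_fastq(path)) == []

    def test_length_mismatch_names_line(self, tmp_path):
        path = write(tmp_path, "b.fastq", "@ok\nACGT\n+\nIIII\n@r2\nACGT\n+\nIII\n")
        with pytest.raises(FormatError, match="line 5"):
            list(fio.read_fastq(path))

    def test_u_and_t_interchangeable_on_input(self):
        read = QualityRead("x", "UACG", (40, 40, 40, 40))
        assert read.sequence == "TACG"


class TestCollapsedFasta:
    def test_underscore_count_dialect(self, tmp_path):
        path = write(tmp_path, "c.fa", ">u1_350\nUACAGUACUGUGAUAACUGAA\n")
        (read,) = list(fio.read_collapsed_fasta(path))
        assert read.count == 350
        assert read.sequence.startswith("TACAGT")
        assert set(read.phred) == {40}

    def test_whitespace_count_dialect(self, tmp_path):
        path = write(tmp_path, "c.fa", ">u2 7\nACGTACGTACGT\n")
        (read,) = list(fio.read_collapsed_fasta(path))
        assert read.count == 7

    def test_missing_count_strict_errors_lenient_defaults(self, tmp_path):
        path = write(tmp_path, "c.fa", ">u3\nACGTACGT\n")
        with pytest.raises(FormatError, match="count"):
            list(fio.read_collapsed_fasta(path))
        (read,) = list(fio.read_collapsed_fasta(path, strict=False))
        assert read.count == 1

    def test_round_trip(self, tmp_path):
        reads = [QualityRead("u1", "ACGTACGT", (40,) * 8, count=12)]
        path = tmp_path / "out.fa"
        fio.write_collapsed_fasta(reads, path)
        (back,) = list(fio.read_collapsed_fasta(path))
        assert (back.sequence, back.count) == ("ACGTACGT", 12)


class TestMatureAnnotations:
    def test_tsv_rows(self, tmp_path):
        path = write(tmp_path, "m.tsv", "hp1\t3p\t44\t65\nhp1\t5p\t6\t27\n")
        out = fio.read_mature_annotations(path)
        assert out["hp1"][0] == MatureInterval("3p", 44, 65)
        assert out["hp1"][1] == MatureInterval("5p", 6, 27)

    def test_gff3_plus_and_minus_strand_conversion(self, tmp_path):
        gff = """\
        ##gff-version 3
        chr1\t.\tmiRNA_primary_transcript\t1001\t1090\t.\t+\t.\tID=MI01;Name=hp-plus
        chr1\t.\tmiRNA\t1006\t1027\t.\t+\t.\tID=MA01;Name=hp-plus-5p;Derives_from=MI01
        chr2\t.\tmiRNA_primary_transcript\t5001\t5090\t.\t-\t.\tID=MI02;Name=hp-minus
        chr2\t.\tmiRNA\t5064\t5085\t.\t-\t.\tID=MA02;Name=hp-minus-5p;Derives_from=MI02
        """
        out = fio.read_mature_annotations(write(tmp_path, "m.gff3", gff))
        assert out["hp-plus"] == (MatureInterval("5p", 6, 27, name="hp-plus-5p"),)
        # minus strand: hairpin-local coordinates count from the hairpin 5' end
        assert out["hp-minus"] == (MatureInterval("5p", 6, 27, name="hp-minus-5p"),)

    def test_interval_outside_hairpin_rejected(self, tmp_path):
        path = write(tmp_path, "m.tsv", "hp1\t3p\t100\t120\n")
        hairpins = {"hp1": Hairpin("hp1", "A" * 90)}
        with pytest.raises(FormatError, match="hp1"):
            fio.read_mature_annotations(path, hairpins=hairpins)


class TestTables:
    def test_snp_table_with_header(self, tmp_path):
        path = write(
            tmp_path,
            "s.tsv",
            "rs_id\thairpin\tposition\tref\talt\nrs1\thp1\t49\tA\tG\n",
        )
        (rec,) = fio.read_snp_table(path)
        assert rec == SNPRecord("rs1", "hp1", 49, "A", "G")
        assert rec.key == ("hp1", 49, "A", "G")

    def test_snp_ref_equal_alt_rejected(self):
        with pytest.raises(FormatError):
            SNPRecord("rs2", "hp1", 3, "A", "a")

    def test_editing_table(self, tmp_path):
        path = write(tmp_path, "e.tsv", "hp1\t49\tA\tG\tDARNED\n")
        out = fio.read_editing_table(path)
        assert out[("hp1", 49, "A", "G")] == "DARNED"


def _site(me_id, hairpin_id, position, ref, alt, category, tallies):
    return MESite(
        me_id=me_id, hairpin_id=hairpin_id, position=position, ref=ref,
        alt=alt, category=category, tallies=tallies,
    )


def _tally(lib, n, mer, fdr):
    return PositionTally(
        hairpin_id="hsa-mir-376a-1", position=49, ref="A", alt="G",
        n=n, mer=mer, p_e=0.01, library=lib, fdr_p=fdr,
    )


class TestSiteReport:
    def test_layout_and_formats(self, tmp_path):
        site = _site(
            "hsa-mir-376a-1_49_A_g", "hsa-mir-376a-1", 49, "A", "G", "A-to-I",
            {"L1": _tally("L1", 25.73, 23.0, 3.2e-17)},
        )
        path = tmp_path / "report.tsv"
        fio.write_site_report([site], ["L1", "L2"], path)
        frame = fio.read_site_report(path)
        row = frame.iloc[0]
        assert row["ME_ID"] == "hsa-mir-376a-1_49_A_g"
        assert row["ref"] == "A" and row["alt"] == "g"
        assert row["L1_MER"] == "23.00"
        assert row["L1_MEP"] == "89.4"
        assert row["L1_FDR_P"] == "3.20E-17"
        # absence convention in the second library
        assert row["L2_MER"] == "0.00"
        assert row["L2_MEP"] == "0.0"
        assert row["L2_FDR_P"] == "1.00E+00"

    def test_fdr_underflow_prints_zero(self, tmp_path):
        site = _site(
            "hsa-mir-376a-1_49_A_g", "hsa-mir-376a-1", 49, "A", "G", "A-to-I",
            {"L1": _tally("L1", 100.0, 90.0, 0.0)},
        )
        path = tmp_path / "r.tsv"
        fio.write_site_report([site], ["L1"], path)
        assert fio.read_site_report(path).iloc[0]["L1_FDR_P"] == "0.00E+00"

    def test_empty_site_list_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        fio.write_site_report([], ["L1"], path)
        frame = fio.read_site_report(path)
        assert len(frame) == 0
        assert list(frame.columns) == [
            *fio.REPORT_FIXED_COLUMNS, "L1_MER", "L1_MEP", "L1_FDR_P",
        ]

    def test_round_trip_recovers_printed_precision(self, tmp_path):
        tally = _tally("L1", 203.4567, 41.239, 1.234e-8)
        site = _site(
            "hsa-mir-376a-1_49_A_g", "hsa-mir-376a-1", 49, "A", "G", "A-to-I",
            {"L1": tally},
        )
        path = tmp_path / "r.tsv"
        fio.write_site_report([site], ["L1"], path)
        row = fio.read_site_report(path).iloc[0]
        assert float(row["L1_MER"]) == pytest.approx(tally.mer, abs=0.005)
        assert float(row["L1_MEP"]) == pytest.approx(100 * tally.p_o, abs=0.05)
        assert float(row["L1_FDR_P"]) == pytest.approx(tally.fdr_p, rel=0.005)


class TestHairpinInvariants:
    def test_overlapping_mature_intervals_rejected(self):
        with pytest.raises(FormatError, match="overlap"):
            Hairpin(
                "hp", "A" * 80,
                (MatureInterval("5p", 10, 40), MatureInterval("3p", 30, 60)),
            )

    def test_mature_position_lookup(self, hairpin):
        interval, offset = hairpin.mature_position(15)
        assert interval.arm == "5p" and offset == 6
        assert hairpin.mature_position(40) is None
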