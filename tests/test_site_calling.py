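from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from oracles import bh_step_up
from miredit.formats_io import Hairpin, MatureInterval, QualityRead
from miredit.hairpin_align import local_align
from miredit.site_calling import (
    PileupRead,
    PositionTally,
    bh_correct,
    call_significant,
    classify,
    merge_libraries,
    name_site,
    phred_to_error,
    pileup,
    position_is_3prime,
    z_statistic,
)


class TestPhredToError:
    def test_phred_twenty_is_one_percent(self):
        assert phred_to_error(20) == 0.01

    def test_formula_values(self):
        assert phred_to_error(30) == pytest.approx(0.001)
        assert phred_to_error(0) == 1.0
        assert phred_to_error(40) == pytest.approx(1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phred_to_error(-1)


class TestZStatistic:
    def test_reference_point(self):
        z, p = z_statistic(0.05, 0.01, 100)
        assert z == pytest.approx(4.0201513, abs=1e-6)
        assert p == pytest.approx(2.908e-5, rel=1e-3)

    def test_null_gives_zero_and_half(self):
        z, p = z_statistic(0.01, 0.01, 250)
        assert z == 0.0 and p == 0.5

    def test_doubling_n_scales_z_by_sqrt_two(self):
        z1, _ = z_statistic(0.2, 0.01, 100)
        z2, _ = z_statistic(0.2, 0.01, 200)
        assert z2 == pytest.approx(z1 * math.sqrt(2))

    def test_closed_form_on_grid(self):
        for p_o in (0.02, 0.05, 0.2, 0.9):
            for p_e in (0.001, 0.01, 0.1):
                for n in (10, 100, 1000):
                    z, p = z_statistic(p_o, p_e, n)
                    expected = (p_o - p_e) / math.sqrt(p_e * (1 - p_e) / n)
                    assert abs(z - expected) < 1e-12
                    assert p == pytest.approx(stats.norm.sf(expected))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            z_statistic(0.1, 0.01, 0)
        with pytest.raises(ValueError):
            z_statistic(0.1, 0.0, 10)

    def test_normal_tail_tracks_exact_binomial_within_factor_three(self):
        # sanity envelope where the normal approximation is standardly
        # adequate: expected count >= 3 and moderate excess (z <= 2)
        for n in (30, 100, 300):
            for p_e in (0.05, 0.1, 0.2):
                if n * p_e < 3:
                    continue
                for dz in (0.0, 1.0, 2.0):
                    k = int(round(n * p_e + dz * math.sqrt(n * p_e * (1 - p_e))))
                    if not 1 <= k <= n:
                        continue
                    _, p = z_statistic(k / n, p_e, n)
                    exact = stats.binom.sf(k - 1, n, p_e)
                    assert max(p / exact, exact / p) < 3.0


class TestBHCorrection:
    def test_single_p_value_unchanged(self):
        assert bh_correct([0.03]) == [pytest.approx(0.03)]

    def test_hand_worked_example(self):
        assert bh_correct([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert bh_correct([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(30):
            p = rng.random(int(rng.integers(1, 40))).tolist()
            assert bh_correct(p) == pytest.approx(bh_step_up(p))

    def test_monotone_and_dominates_raw(self, rng):
        p = rng.random(50).tolist()
        adj = bh_correct(p)
        assert all(a >= r for a, r in zip(adj, p))
        order_raw = np.argsort(p)
        assert all(
            adj[order_raw[i]] <= adj[order_raw[i + 1]] + 1e-15 for i in range(49)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.5])

    def test_empty_family(self):
        assert bh_correct([]) == []


def make_placement(hairpin, sequence, count=1, weight=1.0, phred=40, low_at=None):
    scores = [phred] * len(sequence)
    if low_at is not None:
        scores[low_at] = 5
    read = QualityRead(f"r{hash((sequence, count, weight, low_at)) & 0xFFFF}",
                       sequence, tuple(scores), count=count)
    hit = local_align(read.sequence, hairpin.sequence, read_id=read.read_id,
                      target_id=hairpin.hairpin_id)
    assert hit is not None
    return PileupRead(read, hit, weight)


class TestPileup:
    def mature_read(self, hairpin):
        return hairpin.sequence[9:31]  # the full 5p arm, positions 10..31

    def alt_read(self, hairpin, position=20, alt="G"):
        seq = list(self.mature_read(hairpin))
        idx = position - 10
        assert hairpin.base(position) != alt
        seq[idx] = alt
        return "".join(seq), idx

    def test_direct_counting(self, hairpin):
        alt_seq, _ = self.alt_read(hairpin)
        placements = [
            make_placement(hairpin, self.mature_read(hairpin), count=90),
            make_placement(hairpin, alt_seq, count=10),
        ]
        tallies = pileup(hairpin, placements)
        (tally,) = [t for t in tallies if t.position == 20]
        assert tally.n == pytest.approx(100)
        assert tally.mer == pytest.approx(10)
        assert tally.p_o == pytest.approx(0.10)
        assert tally.ref == hairpin.base(20)

    def test_low_phred_base_excluded_from_n_and_mer(self, hairpin):
        alt_seq, idx = self.alt_read(hairpin)
        placements = [
            make_placement(hairpin, self.mature_read(hairpin), count=90),
            make_placement(hairpin, alt_seq, count=10, low_at=idx),
            make_placement(hairpin, alt_seq, count=5),
        ]
        (tally,) = [t for t in pileup(hairpin, placements) if t.position == 20]
        assert tally.n == pytest.approx(95)  # the low-quality alt bases vanish
        assert tally.mer == pytest.approx(5)

    def test_weighted_contribution(self, hairpin):
        alt_seq, _ = self.alt_read(hairpin)
        placements = [
            make_placement(hairpin, self.mature_read(hairpin), count=90),
            make_placement(hairpin, alt_seq, count=4, weight=0.5),
        ]
        (tally,) = [t for t in pileup(hairpin, placements) if t.position == 20]
        assert tally.mer == pytest.approx(2.0)
        assert tally.n == pytest.approx(92.0)

    def test_zero_weight_reads_ignored(self, hairpin):
        alt_seq, _ = self.alt_read(hairpin)
        placements = [make_placement(hairpin, alt_seq, count=10, weight=0.0)]
        assert pileup(hairpin, placements) == []

    def test_error_floor_applied_to_pe(self, hairpin):
        alt_seq, _ = self.alt_read(hairpin)
        placements = [make_placement(hairpin, alt_seq, count=10, phred=40)]
        (tally,) = [t for t in pileup(hairpin, placements) if t.position == 20]
        assert tally.p_e == 0.01  # floor dominates the phred-40 error 1e-4

    def test_three_prime_addition_denominator_includes_terminating_reads(self, hairpin):
        # 70 reads end at the mature 3' end; 30 carry a non-templated base
        added = next(b for b in "ACGT" if b != hairpin.base(32))
        tail_seq = self.mature_read(hairpin) + added
        placements = [
            make_placement(hairpin, self.mature_read(hairpin), count=70),
            make_placement(hairpin, tail_seq, count=30),
        ]
        (tally,) = [t for t in pileup(hairpin, placements) if t.position == 32]
        assert tally.alt == added
        assert tally.n == pytest.approx(100)
        assert tally.p_o == pytest.approx(0.30)


class TestCallingCriteria:
    def tally(self, mer, p_o, fdr):
        n = mer / p_o
        return PositionTally(
            hairpin_id="hp", position=20, ref="A", alt="G", n=n, mer=mer,
            p_e=0.01, p_value=fdr, fdr_p=fdr,
        )

    def test_each_fixture_rejected_by_exactly_one_criterion(self):
        support_short = self.tally(mer=9, p_o=0.5, fdr=1e-20)
        fraction_short = self.tally(mer=50, p_o=0.04, fdr=1e-20)
        fdr_short = self.tally(mer=50, p_o=0.5, fdr=0.06)
        kept = call_significant(
            [support_short, fraction_short, fdr_short], apply_bh=False
        )
        assert kept == []
        # each fails for its own single reason
        assert support_short.mer < 10 and support_short.p_o >= 0.05
        assert fraction_short.p_o < 0.05 and fraction_short.mer >= 10
        assert fdr_short.fdr_p >= 0.05 and fdr_short.mer >= 10 and fdr_short.p_o >= 0.05

    def test_exemplary_site_retained(self):
        strong = self.tally(mer=23, p_o=0.894, fdr=0.0)
        assert call_significant([strong], apply_bh=False) == [strong]

    def test_bh_family_applied_before_filtering(self):
        # a raw p of 0.02 would pass alpha alone, but corrected across a
        # family of null tests it is inflated to 0.08 and rejected
        raws = [0.02, 0.8, 0.9, 0.95]
        family = [self.tally(mer=50, p_o=0.5, fdr=1.0) for _ in raws]
        for t, p in zip(family, raws):
            t.p_value = p
        kept = call_significant(family, apply_bh=True)
        assert kept == []
        assert family[0].fdr_p == pytest.approx(0.08)


class TestClassification:
    def tally(self, position, ref, alt, hp="syn-mir-hp"):
        return PositionTally(
            hairpin_id=hp, position=position, ref=ref, alt=alt,
            n=100.0, mer=20.0, p_e=0.01, p_value=1e-9, fdr_p=1e-8,
        )

    def test_a_to_i_inside_mature(self, hairpin):
        assert classify(self.tally(20, "A", "G"), hairpin) == "A-to-I"

    def test_c_to_u_inside_mature(self, hairpin):
        assert classify(self.tally(22, "C", "T"), hairpin) == "C-to-U"

    def test_three_prime_categories_past_mature_end(self, hairpin):
        assert classify(self.tally(32, "C", "A"), hairpin) == "3'-A"
        assert classify(self.tally(32, "C", "T"), hairpin) == "3'-U"
        assert classify(self.tally(32, "C", "G"), hairpin) == "3'-Other"

    def test_three_prime_takes_precedence_over_a_to_i(self, hairpin):
        assert classify(self.tally(32, "A", "G"), hairpin) == "3'-Other"

    def test_soft_extension_past_hairpin_end_is_three_prime(self, hairpin):
        assert classify(self.tally(len(hairpin) + 1, "-", "A"), hairpin) == "3'-A"

    def test_internal_insertion_is_other(self, hairpin):
        assert classify(self.tally(15, "-", "G"), hairpin) == "Other"

    def test_non_canonical_substitution_is_other(self, hairpin):
        assert classify(self.tally(20, "T", "G"), hairpin) == "Other"

    def test_snp_table_match_wins_over_a_to_i(self, hairpin):
        snps = {("syn-mir-hp", 20, "A", "G")}
        assert classify(self.tally(20, "A", "G"), hairpin, snp_table=snps) == "SNP"

    def test_pseudo_when_filtered_tally_fails_criteria(self, hairpin):
        t = self.tally(20, "A", "G")
        filtered = PositionTally(
            hairpin_id="syn-mir-hp", position=20, ref="A", alt="G",
            n=5.0, mer=1.0, p_e=0.01, p_value=0.2,
        )
        assert classify(t, hairpin, filtered_tally=filtered, check_pseudo=True) == "Pseudo"
        assert classify(t, hairpin, filtered_tally=None, check_pseudo=True) == "Pseudo"

    def test_not_pseudo_when_filtered_tally_still_significant(self, hairpin):
        t = self.tally(20, "A", "G")
        filtered = PositionTally(
            hairpin_id="syn-mir-hp", position=20, ref="A", alt="G",
            n=90.0, mer=18.0, p_e=0.01, p_value=1e-12,
        )
        assert (
            classify(t, hairpin, filtered_tally=filtered, check_pseudo=True) == "A-to-I"
        )

    def test_unknown_nucleotide_rejected(self, hairpin):
        with pytest.raises(ValueError):
            classify(self.tally(20, "A", "N"), hairpin)

    def test_tail_region_predicate(self, hairpin):
        assert position_is_3prime(hairpin, 32)
        assert position_is_3prime(hairpin, len(hairpin) + 2)
        assert not position_is_3prime(hairpin, 31)  # inside mature
        assert not position_is_3prime(hairpin, 45)  # deep in the loop
        assert position_is_3prime(hairpin, 72)  # just past the 3p arm


class TestNaming:
    @pytest.mark.parametrize(
        "args, expected",
        [
            (("hsa-mir-376a-1", 49, "A", "g"), "hsa-mir-376a-1_49_A_g"),
            (("hsa-mir-378c", 30, "-", "g"), "hsa-mir-378c_30_-_g"),
            (("hsa-mir-125b-1", 25, "C", "u"), "hsa-mir-125b-1_25_C_u"),
            (("hp", 7, "T", "c"), "hp_7_U_c"),  # internal DNA renders as RNA
        ],
    )
    def test_canonical_names(self, args, expected):
        assert name_site(*args) == expected

    def test_identical_ref_and_alt_rejected(self):
        with pytest.raises(ValueError):
            name_site("hp", 5, "A", "a")

    def test_invalid_nucleotides_rejected(self):
        with pytest.raises(ValueError):
            name_site("hp", 5, "X", "g")
        with pytest.raises(ValueError):
            name_site("hp", 5, "A", "-")


class TestMergeLibraries:
    def tally(self, lib, hp, pos, ref="A", alt="G", fdr=1e-9):
        return PositionTally(
            hairpin_id=hp, position=pos, ref=ref, alt=alt, n=100.0, mer=20.0,
            p_e=0.01, library=lib, p_value=fdr, fdr_p=fdr,
        )

    def hairpins(self):
        from miredit.formats_io import Hairpin, MatureInterval

        return {
            hp: Hairpin(hp, "ACGT" * 20, (MatureInterval("5p", 10, 31),))
            for hp in ("hp1", "hp2")
        }

    def test_union_with_zeros_where_absent(self):
        t1 = self.tally("L1", "hp1", 20)
        t2 = self.tally("L2", "hp2", 22)
        sites, n_common = merge_libraries(
            {"L1": [(t1, "A-to-I")], "L2": [(t2, "A-to-I")]},
            {"L1": [t1], "L2": [t2]},
            self.hairpins(),
        )
        assert len(sites) == 2 and n_common == 0
        by_id = {s.me_id: s for s in sites}
        assert by_id["hp1_20_A_g"].tallies.keys() == {"L1"}
        assert by_id["hp1_20_A_g"].significant_in == ("L1",)
        assert by_id["hp1_20_A_g"].position_in_mature == 11

    def test_identical_site_sets_all_common(self):
        t1, t2 = self.tally("L1", "hp1", 20), self.tally("L2", "hp1", 20)
        sites, n_common = merge_libraries(
            {"L1": [(t1, "A-to-I")], "L2": [(t2, "A-to-I")]},
            {"L1": [t1], "L2": [t2]},
            self.hairpins(),
        )
        assert len(sites) == 1 and n_common == 1
        assert sites[0].tallies.keys() == {"L1", "L2"}

    def test_subthreshold_tally_of_other_library_attached(self):
        t1 = self.tally("L1", "hp1", 20)
        weak = self.tally("L2", "hp1", 20, fdr=0.9)
        sites, _ = merge_libraries(
            {"L1": [(t1, "A-to-I")], "L2": []},
            {"L1": [t1], "L2": [weak]},
            self.hairpins(),
        )
        assert sites[0].tallies["L2"] is weak
        assert sites[0].significant_in == ("L1",)

    def test_category_disagreement_resolved_by_smallest_fdr(self):
        t1 = self.tally("L1", "hp1", 20, fdr=1e-3)
        t2 = self.tally("L2", "hp1", 20, fdr=1e-12)
        sites, _ = merge_libraries(
            {"L1": [(t1, "A-to-I")], "L2": [(t2, "SNP")]},
            {"L1": [t1], "L2": [t2]},
            self.hairpins(),
        )
        assert sites[0].category == "SNP"
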