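"""Burden module: locus frequencies, signed-rank test, permutation null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rareburden import burden as bd
from rareburden.cohort import MISSING

from conftest import make_cohort


class TestLocusFreq:
    def test_hand_counted_frequencies_with_missing_excluded(self, hand_cohort):
        """2 het + 1 hom among 10 called cases -> 4/20 = 0.200."""
        pair = bd.locus_freq(hand_cohort, 0)
        assert pair.case_alt_count == 4
        assert pair.case_called_chrom == 20
        assert pair.case_freq == pytest.approx(0.200)
        assert pair.control_freq == pytest.approx(1 / 8)

    def test_het_carriers_over_full_call_cases(self):
        """6 heterozygotes among 264 fully-called cases -> 6/528 -> 0.011."""
        case = [[1]] * 6 + [[0]] * 258
        control = [[0]] * 218
        pair = bd.locus_freq(make_cohort(case, control), 0)
        assert pair.case_called_chrom == 528
        assert round(pair.case_freq, 3) == 0.011

    def test_no_carriers_gives_zero(self):
        pair = bd.locus_freq(make_cohort([[0]] * 5, [[0]] * 5), 0)
        assert pair.case_freq == 0.0 and pair.control_freq == 0.0

    def test_all_missing_group_raises_with_names(self):
        cohort = make_cohort([[1]], [[MISSING]])
        with pytest.raises(ValueError, match="control.*rs0"):
            bd.locus_freq(cohort, 0)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(0)
        case = rng.integers(0, 3, (30, 1))
        control = rng.integers(0, 3, (20, 1))
        base = bd.locus_freq(make_cohort(case, control), 0)
        perm_case = case[rng.permutation(30)]
        perm_control = control[rng.permutation(20)]
        shuffled = bd.locus_freq(make_cohort(perm_case, perm_control), 0)
        assert (base.case_freq, base.control_freq) == (shuffled.case_freq, shuffled.control_freq)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "case,control,expected",
        [
            (0.036, 0.026, "case_higher"),
            (0.003, 0.003, "similar"),
            (0.007, 0.012, "control_higher"),
        ],
    )
    def test_strict_comparison_matches_published_rows(self, case, control, expected):
        pair = bd.LocusFreqPair.from_freqs("G", "v", case, control)
        assert bd.classify_direction(pair, similar_abs_tol=0.0) == expected

    def test_tolerance_widens_the_similar_band(self):
        pair = bd.LocusFreqPair.from_freqs("G", "v", 0.374, 0.376)
        assert bd.classify_direction(pair, similar_abs_tol=0.005) == "similar"


class TestSignedRankStat:
    def test_all_positive_simple_case(self):
        assert bd.signed_rank_stat([1.0, 2.0, 3.0]) == (6.0, 3)

    def test_published_table_gives_w79(self, published_diffs):
        """Midranks over the 14 printed MAF pairs, zero dropped -> W+=79."""
        w, n = bd.signed_rank_stat(published_diffs)
        assert (w, n) == (79.0, 13)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=15)
        w, n = bd.signed_rank_stat(d)
        w_flipped, _ = bd.signed_rank_stat(-d)
        assert w + w_flipped == pytest.approx(n * (n + 1) / 2)

    def test_all_zero_is_undefined(self):
        with pytest.raises(ValueError, match="all differences are zero"):
            bd.signed_rank_stat([0.0, 0.0])

    def test_pratt_ranks_zeros_but_excludes_them(self):
        # |d| = {0, 1, 2}: nonzero ranks become 2 and 3 under Pratt
        w, n = bd.signed_rank_stat([0.0, 1.0, 2.0], zero_policy="pratt")
        assert (w, n) == (5.0, 2)


class TestExactSignFlip:
    def test_three_positive_diffs_exact_tail(self):
        assert bd.exact_signflip_p([1.0, 2.0, 3.0], "greater") == pytest.approx(1 / 8)

    def test_single_diff_is_half(self):
        assert bd.exact_signflip_p([1.0], "greater") == pytest.approx(1 / 2)

    def test_ten_positive_diffs_approach_2_pow_neg10(self):
        assert bd.exact_signflip_p(list(range(1, 11)), "greater") == pytest.approx(1 / 1024)

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError, match="20"):
            bd.exact_signflip_p(np.arange(1, 23, dtype=float), "greater")

    def test_two_sided_is_double_smaller_tail_capped(self):
        d = [1.0, 2.0, -3.0]
        pg = bd.exact_signflip_p(d, "greater")
        pl = bd.exact_signflip_p(d, "less")
        assert bd.exact_signflip_p(d, "two_sided") == pytest.approx(min(1, 2 * min(pg, pl)))


class TestPermutationTest:
    @pytest.mark.parametrize("alternative", ["greater", "two_sided"])
    @pytest.mark.parametrize("zero_policy", ["drop", "pratt"])
    def test_converges_to_exact_oracle(self, published_diffs, alternative, zero_policy):
        """Monte-Carlo p agrees with 2^m enumeration within 3 binomial SE."""
        exact = bd.exact_signflip_p(published_diffs, alternative, zero_policy)
        n_perm = 20_000
        res = bd.permutation_test(
            published_diffs, n_perm=n_perm, seed=99, alternative=alternative, zero_policy=zero_policy
        )
        se = np.sqrt(exact * (1 - exact) / n_perm)
        margin = 3 * se + 1 / (n_perm + 1)  # add-one correction offset
        assert abs(res.empirical_p - exact) <= (2 * margin if alternative == "two_sided" else margin)

    def test_reproducible_given_seed(self, published_pairs):
        a = bd.permutation_test(published_pairs, n_perm=2000, seed=5)
        b = bd.permutation_test(published_pairs, n_perm=2000, seed=5)
        assert a.empirical_p == b.empirical_p

    def test_add_one_correction_keeps_p_positive(self):
        res = bd.permutation_test(list(range(1, 11)), n_perm=200, seed=0)
        assert res.empirical_p >= 1 / 201

    def test_near_median_statistic_gives_central_p(self):
        """Alternating signs put W+ near the null centre: p is ~0.5, not a tail."""
        d = [r * (-1) ** r for r in range(1, 13)]
        exact = bd.exact_signflip_p(d, "greater")
        res = bd.permutation_test(d, n_perm=5000, seed=2, alternative="greater")
        assert 0.3 < exact < 0.7
        assert res.empirical_p == pytest.approx(exact, abs=0.03)

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            bd.permutation_test([1.0, 2.0, 3.0], n_perm=50, seed=0)

    def test_requires_two_nonzero_diffs(self):
        with pytest.raises(ValueError, match="two nonzero"):
            bd.permutation_test([0.0, 0.0, 1.0], n_perm=500, seed=0)

    def test_invalid_alternative_rejected(self):
        with pytest.raises(ValueError, match="alternative"):
            bd.permutation_test([1.0, -2.0, 3.0], n_perm=500, seed=0, alternative="sideways")

    def test_direction_tally_attached_for_pairs(self, published_pairs):
        res = bd.permutation_test(published_pairs, n_perm=500, seed=0)
        assert res.direction_tally == {"case_higher": 10, "control_higher": 3, "similar": 1}


class TestBurdenTestModel:
    def test_fit_from_freq_frame_matches_function_route(self, published_pairs):
        frame = bd.freq_frame(published_pairs)
        res_model = bd.BurdenTest.from_freq_frame(frame).fit(n_perm=1000, seed=3)
        res_func = bd.permutation_test(published_pairs, n_perm=1000, seed=3)
        assert res_model.empirical_p == res_func.empirical_p
        assert res_model.w_plus == res_func.w_plus == 79.0

    def test_summary_mentions_the_key_numbers(self, published_pairs):
        text = bd.BurdenTest(published_pairs).fit(n_perm=1000, seed=3).summary()
        assert "W+ = 79" in text and "10 case-higher" in text


class TestDetectionPower:
    @pytest.mark.parametrize(
        "f,n,expected",
        [(0.005, 304, 0.782), (0.0, 50, 0.0), (1.0, 1, 1.0)],
    )
    def test_values(self, f, n, expected):
        assert bd.detection_power(f, n) == pytest.approx(expected, abs=5e-4)

    def test_strictly_increasing_in_both_arguments(self):
        fs = np.linspace(0.001, 0.05, 25)
        powers = [bd.detection_power(f, 100) for f in fs]
        assert np.all(np.diff(powers) > 0)
        ns = range(1, 50)
        powers_n = [bd.detection_power(0.01, n) for n in ns]
        assert np.all(np.diff(powers_n) > 0)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            bd.detection_power(1.2, 10)
        with pytest.raises(ValueError):
            bd.detection_power(0.1, 0)


class TestCarrierTally:
    def test_hom_and_het_counts_per_group(self):
        case = [[2]] * 16 + [[1]] * 30 + [[0]] * 30
        control = [[2]] * 4 + [[1]] * 10 + [[0]] * 29
        tally = bd.carrier_tally(make_cohort(case, control), 0)
        assert (tally.case_hom, tally.case_n) == (16, 76)
        assert (tally.control_hom, tally.control_n) == (4, 43)
        assert round(tally.case_hom_pct) == 21
        assert round(tally.control_hom_pct, 1) == 9.3

    def test_zero_homozygotes(self):
        tally = bd.carrier_tally(make_cohort([[1]] * 5, [[0]] * 5), 0)
        assert tally.case_hom_pct == 0.0


class TestCaseOnly:
    def test_published_table_yields_six_case_only_genes(self, published_pairs):
        loci = bd.case_only_loci(published_pairs)
        assert len(loci) == 6
        assert bd.case_only_genes(published_pairs) == {
            "CARD6", "DEFB1", "FUT2", "MBL2", "NLRP10", "NOD2",
        }

    def test_empty_input_and_zero_zero_pair(self):
        assert bd.case_only_loci([]) == []
        pair = bd.LocusFreqPair.from_freqs("G", "v", 0.0, 0.0)
        assert bd.case_only_loci([pair]) == []

    def test_count_route_preferred_over_freq_route(self):
        pair = bd.LocusFreqPair.from_counts("G", "v", 1, 10, 0, 10)
        assert bd.case_only_loci([pair]) == [pair]


class TestDigenicCarriers:
    def test_planted_co_carriers_recovered_exactly(self):
        case = [[1, 1, 0], [1, 0, 0], [0, 2, 1], [0, 0, 0]]
        control = [[0, 0, 0], [1, 0, 1]]
        hits = bd.digenic_carriers(make_cohort(case, control))
        assert hits == [
            ("s0", ("rs0", "rs1")),
            ("s2", ("rs1", "rs2")),
            ("s5", ("rs0", "rs2")),
        ]

    def test_no_overlapping_carriers_gives_empty(self):
        hits = bd.digenic_carriers(make_cohort([[1, 0], [0, 1]], [[0, 0]]))
        assert hits == []

    def test_requires_two_loci(self):
        with pytest.raises(ValueError):
            bd.digenic_carriers(make_cohort([[1]], [[0]]), loci=["rs0"])


@given(
    st.lists(
        st.floats(-1, 1, allow_nan=False).filter(lambda x: abs(x) > 1e-6),
        min_size=1,
        max_size=12,
    )
)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_signflip_antisymmetry_holds_for_arbitrary_diffs(diffs):
    """W+(d) + W+(-d) = n(n+1)/2 for any nonzero difference vector."""
    w, n = bd.signed_rank_stat(diffs)
    w_neg, _ = bd.signed_rank_stat([-x for x in diffs])
    assert w + w_neg == pytest.approx(n * (n + 1) / 2)


@given(
    f=st.floats(0, 1, allow_nan=False),
    n=st.integers(1, 2000),
)
@settings(derandomize=True, max_examples=80, deadline=None)
def test_detection_power_stays_in_unit_interval_and_grows_with_n(f, n):
    p = bd.detection_power(f, n)
    assert 0.0 <= p <= 1.0
    assert bd.detection_power(f, n + 1) >= p


def test_locus_freq_pair_validation():
    with pytest.raises(ValueError, match="even"):
        bd.LocusFreqPair.from_counts("G", "v", 1, 11, 0, 10)
    with pytest.raises(ValueError, match="alt count"):
        bd.LocusFreqPair.from_counts("G", "v", 12, 10, 0, 10)
    with pytest.raises(ValueError):
        bd.LocusFreqPair.from_freqs("G", "v", 1.2, 0.0)
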