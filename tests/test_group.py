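"""ICW grading and the longitudinal group statistics, checked against
independent oracles (exact enumeration, binomial tail arithmetic, rank
formulas, hand-evaluated step-up rules)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorconn.group import (clinical_correlation, compute_icw,
                             dc_group_comparison, fdr_bh,
                             icw_group_comparison, mcnemar_exact_p,
                             population_icw_percentage, wilcoxon_paired_p)
from motorconn.series import MOTOR_ROIS


def enumeration_wilcoxon_p(diffs):
    """Independent oracle: P(W+ >= observed) over all sign assignments,
    with midranks on |d| (zeros dropped)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = sum(
        1 for signs in itertools.product((0, 1), repeat=len(d))
        if np.dot(signs, ranks) >= w_obs - 1e-12
    )
    return count / 2 ** len(d)


class TestICW:
    def test_all_six_epochs_flagged_gives_one(self):
        maps = np.ones((6, 5, 5), dtype=bool)
        for m in maps:
            np.fill_diagonal(m, False)
        icw = compute_icw(maps)
        assert icw[0, 1] == 1.0

    def test_never_flagged_gives_zero(self):
        icw = compute_icw(np.zeros((6, 5, 5), dtype=bool))
        assert np.all(icw == 0.0)

    def test_three_of_six_gives_half(self):
        maps = np.zeros((6, 5, 5), dtype=bool)
        maps[:3, 1, 0] = True
        assert compute_icw(maps)[1, 0] == 0.5

    def test_values_are_multiples_of_one_over_n_epochs(self):
        rng = np.random.default_rng(0)
        maps = rng.uniform(size=(6, 5, 5)) > 0.5
        icw = compute_icw(maps)
        np.testing.assert_allclose(icw * 6, np.round(icw * 6), atol=1e-12)

    def test_population_percentages(self):
        ones = np.ones((5, 5))
        zeros = np.zeros((5, 5))
        assert population_icw_percentage([ones] * 4).max() == 100.0
        mixed = population_icw_percentage([ones, ones, zeros, zeros])
        np.testing.assert_array_equal(mixed, np.full((5, 5), 50.0))
        eighteenth = population_icw_percentage([np.full((5, 5), 1 / 6)] * 18)
        np.testing.assert_allclose(eighteenth, 100 / 6, atol=1e-10)


class TestWilcoxon:
    def test_matches_enumeration_on_toy_differences(self):
        """(+1, +2, +3, +4, -1): midrank ties handled exactly."""
        t0 = np.zeros(5)
        t1 = np.array([1.0, 2.0, 3.0, 4.0, -1.0])
        p = wilcoxon_paired_p(t1, t0, alternative="greater")
        assert p == enumeration_wilcoxon_p(t1 - t0)
        assert p == pytest.approx(3 / 32)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 10))
    def test_matches_enumeration_on_random_pairs(self, seed, n):
        rng = np.random.default_rng(seed)
        d = np.round(rng.standard_normal(n), 2)
        p = wilcoxon_paired_p(d, np.zeros(n), alternative="greater")
        assert p == pytest.approx(enumeration_wilcoxon_p(d))

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon

        rng = np.random.default_rng(5)
        d = rng.standard_normal(10)  # continuous: no ties, no zeros
        p = wilcoxon_paired_p(d, np.zeros(10), alternative="greater")
        sp = wilcoxon(d, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(sp)

    def test_all_zero_differences_warn_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            p = wilcoxon_paired_p(np.ones(8), np.ones(8))
        assert p == 1.0

    def test_less_alternative_mirrors_greater(self):
        rng = np.random.default_rng(6)
        d = rng.standard_normal(9)
        p_g = wilcoxon_paired_p(d, np.zeros(9), alternative="greater")
        p_l = wilcoxon_paired_p(-d, np.zeros(9), alternative="less")
        assert p_g == pytest.approx(p_l)


class TestMcNemar:
    def test_binomial_tail_arithmetic(self):
        p, direction = mcnemar_exact_p(0, 10)
        assert p == pytest.approx(2 * 0.5 ** 10)
        assert direction == 1

    def test_symmetric_counts_capped_at_one(self):
        p, direction = mcnemar_exact_p(5, 5)
        assert p == 1.0
        assert direction == 0

    def test_no_discordant_pairs(self):
        assert mcnemar_exact_p(0, 0) == (1.0, 0)

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(0, 10), (3, 9), (7, 2), (1, 1)]:
            table = np.array([[50, b], [c, 40]])
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact_p(b, c)[0] == pytest.approx(expected)


class TestSpearmanAndFDR:
    def test_perfect_monotone(self):
        labels = ("a", "b")
        d = {"alpha": np.zeros((6, 2, 2))}
        d["alpha"][:, 0, 1] = np.arange(6.0)
        res = clinical_correlation(
            d, {"FMA": np.arange(6.0) * 2 + 1}, labels,
            bands=("alpha",), scores=("FMA",))
        row = res.table[(res.table.source == "b") & (res.table.target == "a")]
        assert row.rho.iloc[0] == pytest.approx(1.0)

    def test_anti_monotone(self):
        labels = ("a", "b")
        d = {"alpha": np.zeros((6, 2, 2))}
        d["alpha"][:, 0, 1] = np.arange(6.0)
        res = clinical_correlation(
            d, {"FMA": -np.arange(6.0)}, labels,
            bands=("alpha",), scores=("FMA",))
        row = res.table[(res.table.source == "b") & (res.table.target == "a")]
        assert row.rho.iloc[0] == pytest.approx(-1.0)

    def test_toy_vectors_match_rank_formula(self):
        """rho of (1..5) vs (2,1,4,3,5) from the d^2 formula: 1 - 6*4/120."""
        from scipy.stats import spearmanr

        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 1, 4, 3, 5], float)
        d2 = ((x - y) ** 2).sum()
        expected = 1 - 6 * d2 / (5 * (25 - 1))
        assert spearmanr(x, y).statistic == pytest.approx(expected)
        assert expected == pytest.approx(0.8)

    def test_constant_input_reported_missing(self):
        labels = ("a", "b")
        d = {"alpha": np.zeros((6, 2, 2))}
        res = clinical_correlation(d, {"FMA": np.arange(6.0)}, labels,
                                   bands=("alpha",), scores=("FMA",))
        assert res.table.rho.isna().all()

    def test_fdr_single_p(self):
        adjusted, rejected = fdr_bh([0.03], q=0.05)
        assert adjusted[0] == pytest.approx(0.03)
        assert rejected[0]

    def test_fdr_step_up_hand_evaluation(self):
        adjusted, rejected = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])
        assert rejected.all()

    def test_fdr_all_ones_rejects_nothing(self):
        adjusted, rejected = fdr_bh(np.ones(10), q=0.05)
        assert not rejected.any()
        np.testing.assert_array_equal(adjusted, np.ones(10))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_fdr_adjusted_monotone_in_raw(self, ps):
        adjusted, _ = fdr_bh(ps, q=0.05)
        order = np.argsort(ps)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)
        assert np.all(adjusted >= np.asarray(ps) - 1e-12)


class TestGroupComparisons:
    def test_identical_sessions_nothing_significant(self):
        rng = np.random.default_rng(1)
        dc = {"alpha": rng.uniform(size=(10, 5, 5)),
              "beta": rng.uniform(size=(10, 5, 5))}
        res = dc_group_comparison(dc, dc, MOTOR_ROIS)
        assert (res.table.raw_p == 1.0).all()
        assert res.significant().empty

    def test_mcnemar_on_planted_shift(self):
        rng = np.random.default_rng(2)
        f0 = {"alpha": rng.uniform(size=(18, 6, 5, 5)) < 0.02,
              "beta": rng.uniform(size=(18, 6, 5, 5)) < 0.02}
        f1 = {b: v.copy() for b, v in f0.items()}
        f1["alpha"][:, :, 1, 3] = True  # ipMC -> iM1 saturated at T1
        res = icw_group_comparison(f0, f1, MOTOR_ROIS)
        tbl = res.table
        hit = tbl[(tbl.band == "alpha") & (tbl.source == "ipMC")
                  & (tbl.target == "iM1")]
        assert hit.adj_p.iloc[0] < 0.05
        assert hit.direction.iloc[0] == "increase"
        assert hit.delta_pct_icw.iloc[0] > 90

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(3)
        f0 = {"alpha": rng.uniform(size=(8, 6, 5, 5)) < 0.3,
              "beta": rng.uniform(size=(8, 6, 5, 5)) < 0.3}
        f1 = {b: rng.uniform(size=(8, 6, 5, 5)) < 0.3 for b in f0}
        res = icw_group_comparison(f0, f1, MOTOR_ROIS)
        assert (res.table.adj_p >= res.table.raw_p - 1e-12).all()
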