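"""The statistical battery against hand computations and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cachalot.inference import (
    holm_adjust,
    lm_permutation_test,
    normality_check,
    overdispersion_check,
    pairwise_behaviour_test,
    pearson_cor,
    poisson_glm,
    two_sample_lm,
    type2_deviance_test,
)


class TestPearson:
    def test_perfect_linear(self):
        res = pearson_cor(np.arange(10.0), np.arange(10.0))
        assert res.statistic == pytest.approx(1.0)
        assert res.notes["r_squared"] == pytest.approx(1.0)
        res = pearson_cor([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = pearson_cor([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)
        assert res.notes["t"] == pytest.approx(1.886, abs=1e-3)
        assert res.df == 2

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=15), rng.normal(size=15)
            res = pearson_cor(x, y)
            r, p = stats.pearsonr(x, y)
            assert res.statistic == pytest.approx(r)
            assert res.p_value == pytest.approx(p)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_cor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTwoSampleLm:
    def test_identical_groups(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        res = two_sample_lm(y, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = two_sample_lm(np.array([1.0, 2, 3, 4, 5, 6]), np.array(["a"] * 3 + ["b"] * 3))
        assert res.statistic == pytest.approx(3.674, abs=1e-3)
        assert res.df == 4

    def test_df_for_study_sample_sizes(self):
        y = np.arange(74.0)
        g = np.array(["p1"] * 38 + ["p2"] * 36)
        assert two_sample_lm(y, g).df == 72

    def test_matches_pooled_t_oracle(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(3, 20, 2)
            y = np.concatenate([rng.normal(0, 1, n1), rng.normal(0.5, 1, n2)])
            g = np.array(["a"] * n1 + ["b"] * n2)
            res = two_sample_lm(y, g)
            t, p = stats.ttest_ind(y[g == "b"], y[g == "a"], equal_var=True)
            assert res.statistic == pytest.approx(t)
            assert res.p_value == pytest.approx(p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_lm(np.array([1.0, 2, 3]), np.array(["a", "a", "b"]))


class TestPoissonGlm:
    def test_constant_counts_closed_form(self):
        fit = poisson_glm(np.full(20, 4), np.repeat(["a", "b"], 10))
        assert fit.params[0] == pytest.approx(np.log(4.0), abs=1e-8)
        assert fit.params[1] == pytest.approx(0.0, abs=1e-8)

    def test_fitted_group_means_equal_sample_means(self, rng):
        y = np.concatenate([rng.poisson(3.0, 30), rng.poisson(6.0, 30)])
        g = np.repeat(["a", "b"], 30)
        fit = poisson_glm(y, g)
        mu = fit.fittedvalues
        assert mu[:30].mean() == pytest.approx(y[:30].mean())
        assert mu[30:].mean() == pytest.approx(y[30:].mean())

    def test_log_rate_difference_recovered(self, rng):
        y = np.concatenate([rng.poisson(4.0, 200), rng.poisson(4.0 * np.exp(0.5), 200)])
        fit = poisson_glm(y, np.repeat(["a", "b"], 200))
        assert fit.params[1] == pytest.approx(0.5, abs=0.15)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_glm(np.array([1.0, 2.5, 3.0]), np.array(["a", "b", "a"]))
        with pytest.raises(ValueError):
            poisson_glm(np.array([1, -2, 3]), np.array(["a", "b", "a"]))


class TestOverdispersion:
    def test_ratio_is_chi2_over_residual_df(self, rng):
        y = rng.poisson(4.0, 19)
        fit = poisson_glm(y, np.repeat(["a", "b"], [8, 11]))
        res = overdispersion_check(fit)
        assert res.df == 17  # 19 observations - 2 parameters
        assert res.statistic == pytest.approx(res.notes["pearson_chi2"] / 17)

    def test_equidispersed_ratio_near_one(self, rng):
        y = rng.poisson(5.0, 100)
        fit = poisson_glm(y, rng.choice(["a", "b"], 100))
        assert overdispersion_check(fit).statistic == pytest.approx(1.0, abs=0.3)

    def test_overdispersed_detected(self, rng):
        # negative-binomial counts: variance ~4x the mean
        y = rng.negative_binomial(n=2, p=2.0 / 7.0, size=200)
        fit = poisson_glm(y, rng.choice(["a", "b"], 200))
        res = overdispersion_check(fit)
        assert res.statistic > 1.0
        assert res.p_value < 0.05


class TestType2Deviance:
    def test_single_predictor_equals_full_vs_intercept_lr(self, rng):
        y = rng.poisson(4.0, 40)
        g = rng.choice(["a", "b"], 40)
        full = poisson_glm(y, g)
        null = poisson_glm(y, np.zeros(40))
        res = type2_deviance_test(full, null)
        assert res.statistic == pytest.approx(2.0 * (full.llf - null.llf), abs=1e-10)
        assert res.df == 1

    def test_null_p_values_uniform(self):
        """With no true effect the LR p-values are Uniform(0,1) across seeds."""
        pvals = []
        for s in range(200):
            r = np.random.default_rng(s)
            y = r.poisson(4.0, 60)
            g = r.choice(["a", "b"], 60)
            pvals.append(type2_deviance_test(poisson_glm(y, g), poisson_glm(y, np.zeros(60))).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficient_design_rejected(self, rng):
        import statsmodels.api as sm

        y = rng.poisson(4.0, 30)
        x = rng.normal(size=30)
        exog = sm.add_constant(np.column_stack([x, x]))  # duplicated predictor
        full = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
        null = sm.GLM(y, np.ones((30, 1)), family=sm.families.Poisson()).fit()
        with pytest.raises(ValueError):
            type2_deviance_test(full, null)


class TestPermutationTest:
    def test_add_one_floor_when_observed_dominates(self, rng):
        x = np.repeat(["a", "b"], 20)
        y = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(50, 0.1, 20)])
        res = lm_permutation_test(y, x, B=1000, seed=1)
        assert res.p_value == pytest.approx(1.0 / 1001.0)

    def test_reproducible_for_fixed_seed(self, rng):
        y, x = rng.normal(size=30), rng.choice(["a", "b", "c"], 30)
        a = lm_permutation_test(y, x, B=500, seed=9)
        b = lm_permutation_test(y, x, B=500, seed=9)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_p_bounded_below(self, rng):
        y, x = rng.normal(size=12), rng.normal(size=12)
        res = lm_permutation_test(y, x, B=50, seed=0)
        assert res.p_value >= 1.0 / 51.0

    def test_bad_arguments_rejected(self, rng):
        with pytest.raises(ValueError):
            lm_permutation_test(rng.normal(size=10), rng.normal(size=10), B=0, seed=0)
        with pytest.raises(ValueError):
            lm_permutation_test(np.array([1.0, 2.0]), np.array([1.0, 2.0]), B=10, seed=0)


class TestHolm:
    def test_hand_computed_examples(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])
        assert holm_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.6, 0.6, 0.6])

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(2, 12)))
            expected = multipletests(p, method="holm")[1]
            assert holm_adjust(p) == pytest.approx(expected)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_never_below_raw_and_permutation_invariant(self, pvals):
        p = np.array(pvals)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert holm_adjust(p[perm]) == pytest.approx(adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestPairwise:
    def test_four_groups_give_six_cells(self, rng):
        y = rng.normal(size=40)
        g = np.repeat(["hunting", "moving", "resting", "socialising"], 10)
        matrix = pairwise_behaviour_test(y, g)
        assert len(matrix.table) == 6
        cell = matrix.cell("moving", "hunting")
        assert cell["F"] == pytest.approx(cell["t"] ** 2)

    def test_identical_groups_not_significant(self):
        y = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        g = np.repeat(["a", "b", "c"], 4)
        matrix = pairwise_behaviour_test(y, g)
        assert (matrix.table["p_holm"] > 0.9).all()

    def test_single_shifted_group_flags_its_pairs_only(self, rng):
        depths = np.concatenate([
            rng.normal(1700, 100, 20),  # hunting: 300 m deeper
            rng.normal(1400, 100, 20),
            rng.normal(1400, 100, 20),
            rng.normal(1400, 100, 20),
        ])
        g = np.repeat(["hunting", "moving", "resting", "socialising"], 20)
        matrix = pairwise_behaviour_test(depths, g)
        sig = matrix.table[matrix.table["significant"]]
        assert len(sig) == 3
        assert all("hunting" in {r.group_a, r.group_b} for r in sig.itertuples())

    def test_small_group_dropped_with_warning(self, rng):
        y = np.concatenate([rng.normal(size=10), [5.0]])
        g = np.array(["a"] * 5 + ["b"] * 5 + ["c"])
        matrix = pairwise_behaviour_test(y, g)
        assert matrix.groups == ["a", "b"]
        assert matrix.table.attrs["dropped_groups"] == ["c"]


class TestNormalityCheck:
    def test_null_p_values_uniform(self):
        pvals = [
            normality_check(np.random.default_rng(s).normal(size=100)).p_value
            for s in range(200)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_heavy_tails_detected(self):
        pvals = [
            normality_check(np.random.default_rng(s).standard_t(df=1, size=100)).p_value
            for s in range(200)
        ]
        assert np.median(pvals) < 0.01

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_check(np.ones(50))
        with pytest.raises(ValueError):
            normality_check(rng.normal(size=6000))
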