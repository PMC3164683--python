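import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pedrecomb.age_stats import (adjusted_regression, age_categories,
                                 age_category_tests, family_adjust,
                                 mixed_model, p_chr_at_least_two,
                                 permutation_test, rank_correlation,
                                 sign_test, spline_fit,
                                 variation_among_parents)

from .oracles import binomial_at_least


def _cohort_counts(seed, n_mothers=40, per_mother=3, slope=-0.5,
                   mother_sd=0.0, base=22.0):
    """Counts ~ Poisson(base + slope*age) + mother effect; ages spread
    within family."""
    rng = np.random.default_rng(seed)
    mothers = np.repeat([f"m{i}" for i in range(n_mothers)], per_mother)
    first = rng.uniform(19, 33, n_mothers)
    ages = np.repeat(first, per_mother) + np.tile(
        np.arange(per_mother) * 3.0, n_mothers) + rng.random(n_mothers * per_mother)
    mu = np.maximum(0.5, base + slope * ages)
    counts = rng.poisson(mu).astype(float)
    if mother_sd > 0:
        counts += np.repeat(rng.normal(0, mother_sd, n_mothers), per_mother)
    return counts, ages, mothers


class TestFamilyAdjust:
    def test_two_child_example(self):
        out = family_adjust([40, 44], ["m", "m"])
        np.testing.assert_allclose(out, [-2.0, 2.0])

    def test_singleton_group_is_zero(self):
        np.testing.assert_allclose(family_adjust([37], ["m"]), [0.0])

    def test_projection_and_zero_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(40, 5, 60)
        groups = rng.integers(0, 12, 60)
        once = family_adjust(vals, groups)
        np.testing.assert_allclose(family_adjust(once, groups), once,
                                   atol=1e-12)
        assert abs(once.mean()) < 1e-9
        for g in np.unique(groups):
            assert abs(once[groups == g].mean()) < 1e-9


class TestAdjustedRegression:
    def test_recovers_generating_slope(self):
        counts, ages, mothers = _cohort_counts(seed=5, slope=-0.5)
        res = adjusted_regression(counts, ages, mothers, n_perm=500, seed=1)
        x = family_adjust(ages, mothers)
        se = np.sqrt(np.var(counts - np.polyval(
            np.polyfit(x, family_adjust(counts, mothers), 1), x))
            / np.sum((x - x.mean()) ** 2))
        assert abs(res.slope - (-0.5)) < 2 * se
        assert res.p_perm < 0.05

    def test_constant_response_degenerate(self):
        res = adjusted_regression([40.0] * 6, [20, 25, 30, 22, 27, 32],
                                  ["a"] * 3 + ["b"] * 3, n_perm=10)
        assert res.degenerate and res.slope == 0.0 and res.pearson_r == 0.0

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            adjusted_regression([1, 2, 3], [20, 25, 30], ["a", "b", "c"])


class TestMixedModel:
    def test_collapses_to_ols_without_mother_variance(self):
        counts, ages, mothers = _cohort_counts(seed=7, mother_sd=0.0)
        mm = mixed_model(counts, ages, mothers, n_perm=20, seed=0)
        ols = scipy.stats.linregress(ages, counts)
        assert mm.slope_age == pytest.approx(ols.slope, abs=0.02)
        assert mm.var_mother < mm.var_residual

    def test_recovers_slope_with_mother_effects(self):
        counts, ages, mothers = _cohort_counts(seed=11, slope=-0.4,
                                               mother_sd=3.0)
        mm = mixed_model(counts, ages, mothers, n_perm=50, seed=0)
        # SE from the parametric fit; recovery within 2 SE
        se = max(0.05, abs(mm.slope_age / max(
            scipy.stats.norm.isf(mm.p_parametric / 2), 1e-6)))
        assert abs(mm.slope_age - (-0.4)) < 2 * max(se, 0.1)
        assert mm.var_mother > 0.5

    def test_uncorrelated_covariate_leaves_slope(self):
        c3, a3, m3 = _cohort_counts(seed=13, slope=-0.4, n_mothers=20,
                                    per_mother=3)
        c4, a4, m4 = _cohort_counts(seed=14, slope=-0.4, n_mothers=20,
                                    per_mother=4)
        counts = np.concatenate([c3, c4])
        ages = np.concatenate([a3, a4])
        mothers = np.concatenate([m3, np.char.add("x", m4)])
        base = mixed_model(counts, ages, mothers, n_perm=10, seed=0)
        with_cov = mixed_model(counts, ages, mothers,
                               n_children_covariate=True, n_perm=10, seed=0)
        assert with_cov.slope_n_children is not None
        assert abs(with_cov.slope_age - base.slope_age) < 0.15

    def test_requires_two_mothers(self):
        with pytest.raises(ValueError):
            mixed_model([1, 2], [20, 25], ["m", "m"])


class TestSpline:
    def test_linear_truth_gives_flat_spline(self):
        counts, ages, mothers = _cohort_counts(seed=17, slope=-0.5)
        fit = spline_fit(counts, ages, mothers, n_perm=20, seed=0)
        # curvature variance is small relative to residual variance
        assert fit.var_spline < fit.var_residual
        line = np.polyval(np.polyfit(ages, counts, 1), ages)
        assert np.max(np.abs(fit.predict(ages) - line)) < 2.0
        assert fit.p_vs_linear > 0.05

    def test_knee_truth_beats_line(self):
        rng = np.random.default_rng(23)
        mothers = np.repeat([f"m{i}" for i in range(40)], 3)
        ages = np.repeat(rng.uniform(19, 33, 40), 3) + np.tile([0, 3, 6], 40)
        truth = np.where(ages < 28, 45 - 0.1 * ages, 45 - 0.1 * 28
                         - 1.5 * (ages - 28))
        counts = truth + rng.normal(0, 1.5, len(ages))
        fit = spline_fit(counts, ages, mothers, n_perm=20, seed=0)
        line = np.polyval(np.polyfit(ages, counts, 1), ages)
        rmse_spline = np.sqrt(np.mean((fit.predict(ages) - truth) ** 2))
        rmse_line = np.sqrt(np.mean((line - truth) ** 2))
        assert rmse_spline < rmse_line

    def test_needs_distinct_ages(self):
        with pytest.raises(ValueError):
            spline_fit([1, 2, 3, 4], [20, 20, 25, 25], ["a", "a", "b", "b"])


class TestPermutationMachinery:
    def test_constant_statistic_p_one(self):
        df = pd.DataFrame({"age_at_birth": [1.0, 2, 3, 4],
                           "parent_id": list("aabb")})
        _, p = permutation_test(lambda d: 1.0, df, "across_transmissions",
                                n_perm=99, seed=0)
        assert p == 1.0

    def test_single_permutation_add_one_rule(self):
        df = pd.DataFrame({"age_at_birth": [1.0, 2, 3, 4, 5, 6],
                           "parent_id": list("aaabbb")})
        stat = lambda d: float(d["age_at_birth"].iloc[0])
        ps = {permutation_test(stat, df, "across_transmissions", n_perm=1,
                               seed=s)[1] for s in range(30)}
        assert ps <= {0.5, 1.0}

    def test_unknown_scheme_rejected(self):
        df = pd.DataFrame({"age_at_birth": [1.0, 2], "parent_id": ["a", "b"]})
        with pytest.raises(ValueError):
            permutation_test(lambda d: 0.0, df, "bootstrap")

    def test_within_family_preserves_group_multisets(self):
        df = pd.DataFrame({"age_at_birth": [1.0, 2, 3, 10, 20, 30],
                           "parent_id": list("aaabbb")})
        seen = []
        def stat(d):
            seen.append(d.groupby("parent_id")["age_at_birth"].sum().tolist())
            return 0.0
        permutation_test(stat, df, "within_family", n_perm=20, seed=1)
        assert all(s == [6.0, 60.0] for s in seen)

    def test_reproducible_under_seed(self):
        counts, ages, mothers = _cohort_counts(seed=29)
        a = adjusted_regression(counts, ages, mothers, n_perm=200, seed=9)
        b = adjusted_regression(counts, ages, mothers, n_perm=200, seed=9)
        assert a.p_perm == b.p_perm


class TestSignTest:
    def test_thirteen_of_thirteen(self):
        assert sign_test(13, 13) == pytest.approx(1.22e-4, rel=5e-3)

    @pytest.mark.parametrize("k,expected", [(1, 0.5), (2, 0.25)])
    def test_small_cases(self, k, expected):
        assert sign_test(k, k) == pytest.approx(expected)

    def test_all_negative_is_half_power_k(self):
        for k in range(1, 20):
            assert sign_test(k, k) == pytest.approx(0.5 ** k, rel=1e-12)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            sign_test(5, 3)


class TestPChrFormula:
    def test_reference_values(self):
        tail, p_chr = p_chr_at_least_two(22, 0.0355)
        assert tail == pytest.approx(0.182, abs=0.001)
        assert p_chr == pytest.approx(0.0455, abs=0.0005)

    def test_matches_binomial_summation_oracle(self):
        tail, p_chr = p_chr_at_least_two(10, 0.1)
        assert tail == pytest.approx(binomial_at_least(2, 10, 0.1), rel=1e-12)
        assert p_chr == pytest.approx(tail * 0.25, rel=1e-12)

    def test_vanishes_as_p_to_zero(self):
        tail, p_chr = p_chr_at_least_two(22, 1e-9)
        assert p_chr < 1e-12

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            p_chr_at_least_two(22, 0.0)


class TestRankCorrelation:
    def test_perfect_monotone(self):
        rho, _ = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40], n_perm=10)
        assert rho == pytest.approx(1.0)

    def test_reversal_negates(self):
        x = [1, 3, 2, 5, 4, 6]
        y = [2, 1, 4, 3, 6, 5]
        rho1, _ = rank_correlation(x, y, n_perm=10)
        rho2, _ = rank_correlation(x, [-v for v in y], n_perm=10)
        assert rho1 == pytest.approx(-rho2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 2], [1, 2, 3])


class TestAgeCategories:
    def test_boundary_conventions(self):
        np.testing.assert_array_equal(age_categories([24.9, 25.0, 30.0, 35.0]),
                                      [0, 1, 2, 3])

    def test_strong_trend_significant(self):
        counts, ages, mothers = _cohort_counts(seed=31, slope=-0.8)
        out = age_category_tests(counts, ages, n_perm=400, seed=0)
        assert out["anova_p"] < 0.01
        assert out["kruskal_p"] < 0.01
        assert out["per_category"]["n"].sum() == len(counts)

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValueError):
            age_category_tests([1, 2, 3], [26, 27, 28], n_perm=10)


class TestVariationAmongParents:
    def test_shifted_parent_detected(self):
        rng = np.random.default_rng(37)
        parents = np.repeat([f"p{i}" for i in range(6)], 4)
        counts = rng.normal(25, 3, 24)
        counts[:4] += 10.0
        f, p = variation_among_parents(counts, parents, n_perm=400, seed=0)
        assert p < 0.01

    def test_singleton_parents_rejected(self):
        with pytest.raises(ValueError):
            variation_among_parents([1, 2, 3], ["a", "b", "c"])
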