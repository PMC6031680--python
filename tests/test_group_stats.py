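"""Group assignment, ANCOVA, post-hoc contrasts, partial correlation, power."""

import numpy as np
import pytest
from scipy import stats

from plvnet.group_stats import (ancova_group_test, anova_power,
                                assign_groups, bonferroni_threshold,
                                cohens_f_from_eta_sq, manova_group_test,
                                partial_correlation, posthoc_pairwise)


class TestAssignGroups:
    def test_quartiles_of_1_to_100(self):
        labels = assign_groups(np.arange(1, 101))
        # inclusive linear interpolation: Q1 = 25.75, Q3 = 75.25
        assert (labels[:25] == "low").all()
        assert (labels[25:75] == "middle").all()
        assert (labels[75:] == "high").all()

    def test_boundary_values_go_to_outer_groups(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 6.0])
        labels = assign_groups(x)
        q1, q3 = np.percentile(x, [25, 75])
        assert (labels[x <= q1] == "low").all()
        assert (labels[x >= q3] == "high").all()

    def test_cohort_scale_split_is_roughly_quartered(self, rng):
        x = rng.normal(42, 11, size=153)
        labels = assign_groups(x)
        n_low = (labels == "low").sum()
        n_high = (labels == "high").sum()
        assert 0 < n_low and 0 < n_high
        assert abs((n_low + n_high) - len(x) / 2) <= 4

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(np.full(20, 7.0))
        with pytest.raises(ValueError):
            assign_groups(np.arange(5))  # too few


class TestBonferroni:
    @pytest.mark.parametrize("m,expect", [(16, 0.003125), (1, 0.05)])
    def test_known_families(self, m, expect):
        assert bonferroni_threshold(0.05, m) == expect

    def test_six_decimal_thresholds(self):
        assert round(bonferroni_threshold(0.05, 314), 6) == 0.000159
        assert round(bonferroni_threshold(0.05, 60), 6) == 0.000833

    def test_invalid_family(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _ancova_oracle(y, groups, covs):
    """From-scratch normal-equations ANCOVA: F and partial eta squared."""
    y = np.asarray(y, float)
    levels = sorted(set(groups), key=list(groups).index)
    dummies = np.column_stack([
        (np.asarray(groups) == lvl).astype(float) for lvl in levels[1:]
    ])
    X_full = np.column_stack([np.ones(len(y)), dummies, covs])
    X_red = np.column_stack([np.ones(len(y)), covs])

    def sse(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    sse_f, sse_r = sse(X_full), sse(X_red)
    q = dummies.shape[1]
    df_err = len(y) - X_full.shape[1]
    F = ((sse_r - sse_f) / q) / (sse_f / df_err)
    eta = (sse_r - sse_f) / (sse_r - sse_f + sse_f)
    p = stats.f.sf(F, q, df_err)
    return F, eta, p, q, df_err


class TestAncova:
    def test_matches_normal_equations_oracle(self, rng):
        n = 9
        groups = np.repeat(["low", "middle", "high"], 3)
        covs = rng.standard_normal((n, 2))
        y = rng.standard_normal(n) + covs @ [0.5, -0.3]
        res = ancova_group_test(y, groups, covs)
        F, eta, p, q, df_err = _ancova_oracle(y, groups, covs)
        assert res.f_stat == pytest.approx(F, abs=1e-10)
        assert res.partial_eta_sq == pytest.approx(eta, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.df_effect == q and res.df_error == df_err

    def test_two_groups_no_covariates_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 15)
        y = np.concatenate([a, b])
        groups = ["low"] * 12 + ["high"] * 15
        res = ancova_group_test(y, groups)
        t, _ = stats.ttest_ind(a, b)  # pooled-variance t
        assert res.f_stat == pytest.approx(t ** 2, rel=1e-10)

    def test_null_type_one_error_rate(self, rng):
        n_rep, alpha = 2000, 0.05
        rejections = 0
        groups = np.repeat(["low", "middle", "high"], 10)
        for _ in range(n_rep):
            y = rng.standard_normal(30)
            cov = rng.standard_normal((30, 1))
            res = ancova_group_test(y, groups, cov)
            rejections += res.p_value < alpha
        assert rejections / n_rep == pytest.approx(alpha, abs=0.01)

    def test_eta_invariant_to_affine_response_rescaling(self, rng):
        y = rng.standard_normal(24)
        groups = np.repeat(["low", "middle", "high"], 8)
        cov = rng.standard_normal((24, 1))
        e1 = ancova_group_test(y, groups, cov).partial_eta_sq
        e2 = ancova_group_test(3.7 * y - 11.0, groups, cov).partial_eta_sq
        assert e1 == pytest.approx(e2, abs=1e-12)

    def test_degenerate_designs_rejected(self, rng):
        y = rng.standard_normal(10)
        with pytest.raises(ValueError):
            ancova_group_test(y, ["low"] * 9 + ["high"], None)
        cov = np.ones((10, 1))  # collinear with the intercept
        with pytest.raises(ValueError):
            ancova_group_test(y, ["low"] * 5 + ["high"] * 5, cov)


class TestPosthoc:
    def test_identical_means_give_large_adjusted_p(self, rng):
        y = np.tile(rng.standard_normal(10), 3)
        groups = np.repeat(["low", "middle", "high"], 10)
        pw = posthoc_pairwise(y, groups)
        assert all(c.p_adjusted == 1.0 for c in pw.values())

    def test_low_high_shift_is_smallest_pair(self, rng):
        y = np.concatenate([
            rng.normal(0, 1, 15), rng.normal(0, 1, 15),
            rng.normal(2.0, 1, 15),
        ])
        groups = np.repeat(["low", "middle", "high"], 15)
        pw = posthoc_pairwise(y, groups)
        p_lh = pw[("low", "high")].p_adjusted
        assert p_lh == min(c.p_adjusted for c in pw.values())
        assert pw[("low", "high")].diff > 0

    def test_adjusted_p_capped_at_one(self, rng):
        y = rng.standard_normal(30)
        groups = np.repeat(["low", "middle", "high"], 10)
        pw = posthoc_pairwise(y, groups)
        assert all(0 <= c.p_adjusted <= 1 for c in pw.values())

    def test_covariate_adjustment_changes_contrast(self, rng):
        groups = np.repeat(["low", "high"], 20)
        cov = np.where(np.asarray(groups) == "high", 1.0, 0.0) \
            + rng.normal(0, 0.3, 40)
        y = 2.0 * cov + rng.normal(0, 0.3, 40)  # group effect via cov only
        raw = posthoc_pairwise(y, groups)[("low", "high")]
        adj = posthoc_pairwise(y, groups, cov[:, None])[("low", "high")]
        assert abs(adj.diff) < abs(raw.diff)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            posthoc_pairwise(np.arange(5.0), ["low", "high", "high",
                                              "high", "high"])


class TestPartialCorrelation:
    def test_empty_covariates_reduce_to_pearson(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        res = partial_correlation(x, y)
        r, p = stats.pearsonr(x, y)
        assert res.r_partial == pytest.approx(r, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_variable_explained_by_covariate_decorrelates(self, rng):
        z = rng.standard_normal(60)
        x = rng.standard_normal(60)
        y = z + 1e-6 * rng.standard_normal(60)  # ~ the covariate itself
        res = partial_correlation(x, y, z[:, None])
        assert abs(res.r_partial) < 0.2

    def test_exactly_constant_residuals_raise(self, rng):
        z = rng.standard_normal(30)
        x = rng.standard_normal(30)
        with pytest.raises(ValueError):
            partial_correlation(x, z.copy(), z[:, None])

    def test_matches_two_stage_regression_oracle(self, rng):
        n = 30
        Z = rng.standard_normal((n, 3))
        x = Z @ [1.0, -0.5, 0.2] + rng.standard_normal(n)
        y = Z @ [0.3, 0.8, -1.0] - 0.4 * x + rng.standard_normal(n)
        res = partial_correlation(x, y, Z)
        # oracle: residualize both via explicit normal equations, then
        # plain Pearson with t on n - k - 2 df
        D = np.column_stack([np.ones(n), Z])
        H = D @ np.linalg.solve(D.T @ D, D.T)
        rx, ry = x - H @ x, y - H @ y
        r_o = float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
        assert res.r_partial == pytest.approx(r_o, abs=1e-12)
        df = n - 3 - 2
        t = r_o * np.sqrt(df / (1 - r_o ** 2))
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), df),
                                            abs=1e-12)
        assert res.n == n and res.n_covariates == 3

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        n = 40
        Z = rng.standard_normal((n, 2))
        x = Z @ [0.7, -0.2] + rng.standard_normal(n)
        y = 0.5 * x + Z @ [0.1, 0.9] + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "c0": Z[:, 0], "c1": Z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c0", "c1"])
        res = partial_correlation(x, y, Z)
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]),
                                              abs=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]),
                                            abs=1e-9)

    def test_insufficient_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_correlation(np.arange(4.0), np.arange(4.0),
                                rng.standard_normal((4, 2)))


def _power_oracle(f, n, k, alpha):
    """Poisson mixture of central F tail probabilities."""
    df1, df2 = k - 1, n - k
    lam = f ** 2 * n
    fcrit = stats.f.ppf(1 - alpha, df1, df2)
    power, j = 0.0, 0
    while j < 500:
        w = stats.poisson.pmf(j, lam / 2)
        power += w * stats.f.sf(fcrit * df1 / (df1 + 2 * j), df1 + 2 * j, df2)
        j += 1
    return power


class TestAnovaPower:
    def test_zero_effect_power_equals_alpha(self):
        assert anova_power(0.0, 60, 3, alpha=0.05) == pytest.approx(0.05,
                                                                    abs=1e-9)

    def test_monotone_in_n_and_effect_size(self):
        p_n = [anova_power(0.25, n, 3) for n in (30, 60, 120, 240)]
        assert all(a < b for a, b in zip(p_n, p_n[1:]))
        p_f = [anova_power(f, 100, 3) for f in (0.1, 0.2, 0.4)]
        assert all(a < b for a, b in zip(p_f, p_f[1:]))

    def test_matches_poisson_mixture_oracle(self):
        val = anova_power(0.25, 153, 3, alpha=0.05)
        assert val == pytest.approx(_power_oracle(0.25, 153, 3, 0.05),
                                    abs=1e-4)

    def test_invalid_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            anova_power(0.2, 3, 3)
        with pytest.raises(ValueError):
            anova_power(-0.1, 30, 3)

    def test_eta_to_f_conversion(self):
        assert cohens_f_from_eta_sq(0.5) == pytest.approx(1.0)
        assert cohens_f_from_eta_sq(0.0) == 0.0


def test_manova_wilks_smoke(rng):
    n = 45
    groups = np.repeat(["low", "middle", "high"], 15)
    Y = rng.standard_normal((n, 4))
    Y[30:, 0] += 1.5
    lam, F, df1, df2, p = manova_group_test(Y, groups)
    assert 0 < lam < 1 and F > 0 and 0 <= p <= 1
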