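"""Covariate-adjusted group statistics for network indices.

Implements the statistical surface of a quartile-split trauma cohort:

* group assignment by 25%/75% quantiles of the trauma-questionnaire total
  (inclusive linear-interpolation convention; boundary ties go to the outer
  groups);
* per-index ANCOVA: a general linear model with the group factor plus
  continuous covariates (state/trait anxiety, depression, ADHD scores),
  F-test for the group effect and partial eta squared
  ``SS_group / (SS_group + SS_error)``; an optional Wilks-lambda
  multivariate test across several indices;
* Bonferroni family-wise control (``alpha / m``);
* covariate-adjusted post-hoc pairwise contrasts with the p-value
  multiplied by the number of pairs and capped at 1;
* partial Pearson correlation by residualization, with the t-based
  p-value on ``n - k - 2`` degrees of freedom;
* ANOVA power from the noncentral F distribution
  (``lambda = f^2 n_total``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

GROUP_ORDER = ("low", "middle", "high")


@dataclass
class StatsResult:
    """Omnibus covariate-adjusted group test for one index."""

    index: str
    band: str | None
    f_stat: float
    df_effect: int
    df_error: int
    p_value: float
    partial_eta_sq: float
    adjusted_alpha: float | None = None
    pairwise: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool | None:
        if self.adjusted_alpha is None:
            return None
        return self.p_value < self.adjusted_alpha


@dataclass
class PairwiseComparison:
    """Covariate-adjusted contrast between two groups."""

    pair: tuple[str, str]
    diff: float  # adjusted mean of second minus first
    p_raw: float
    p_adjusted: float


@dataclass
class CorrelationResult:
    """Partial Pearson correlation of two variables given covariates."""

    r_partial: float
    p_value: float
    n: int
    n_covariates: int
    x_name: str | None = None
    y_name: str | None = None
    band: str | None = None


def assign_groups(ctq_totals) -> np.ndarray:
    """Quartile split into low / middle / high groups.

    Quartiles use the inclusive linear-interpolation convention
    (numpy's default percentile); values at a cut point go to the outer
    group: low is ``<= Q1``, high is ``>= Q3``.
    """
    x = np.asarray(ctq_totals, dtype=float)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("need a 1-D vector of at least 8 scores")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    if q1 == q3:
        raise ValueError("degenerate quartiles (scores nearly constant)")
    labels = np.full(len(x), "middle", dtype=object)
    labels[x <= q1] = "low"
    labels[x >= q3] = "high"
    return labels


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise error control: adjusted alpha = alpha / m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


def _stats_frame(values, groups, covariates) -> tuple[pd.DataFrame, list[str]]:
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(y) != len(g):
        raise ValueError("values and groups must align")
    if covariates is None:
        cov = pd.DataFrame(index=np.arange(len(y)))
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.reset_index(drop=True)
    else:
        cov = pd.DataFrame(np.asarray(covariates, dtype=float))
        cov.columns = [f"cov{i}" for i in range(cov.shape[1])]
    if len(cov) != len(y):
        raise ValueError("covariates must align with values")
    present = [lvl for lvl in GROUP_ORDER if lvl in set(g)]
    present += sorted(set(g) - set(GROUP_ORDER))
    df = pd.DataFrame({"y": y, "group": pd.Categorical(g, categories=present)})
    names = list(cov.columns)
    for c in names:
        df[c] = cov[c].to_numpy(dtype=float)
    return df, names


def ancova_group_test(values, groups, covariates=None,
                      index: str = "value", band: str | None = None,
                      adjusted_alpha: float | None = None) -> StatsResult:
    """GLM group comparison adjusted for continuous covariates.

    With no covariates and two groups the F statistic reduces to the square
    of the pooled-variance two-sample t statistic.
    """
    df, cov_names = _stats_frame(values, groups, covariates)
    counts = df["group"].value_counts()
    if (counts < 2).any():
        raise ValueError(f"every group needs >= 2 subjects, got\n{counts}")
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    rhs = " + ".join(["C(group)"] + cov_names) if cov_names else "C(group)"
    model = smf.ols(f"y ~ {rhs}", data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(
            model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates?)")
    table = sm.stats.anova_lm(model, typ=2)
    ss_group = float(table.loc["C(group)", "sum_sq"])
    ss_error = float(table.loc["Residual", "sum_sq"])
    return StatsResult(
        index=index,
        band=band,
        f_stat=float(table.loc["C(group)", "F"]),
        df_effect=int(table.loc["C(group)", "df"]),
        df_error=int(table.loc["Residual", "df"]),
        p_value=float(table.loc["C(group)", "PR(>F)"]),
        partial_eta_sq=ss_group / (ss_group + ss_error),
        adjusted_alpha=adjusted_alpha,
    )


def manova_group_test(value_matrix, groups, covariates=None):
    """Wilks-lambda multivariate group test across several indices.

    Optional companion to the per-index ANCOVAs (which remain the primary
    surface since published results are reported per index).  Returns
    ``(wilks_lambda, F, df1, df2, p)``.
    """
    from statsmodels.multivariate.manova import MANOVA

    Y = np.asarray(value_matrix, dtype=float)
    df, cov_names = _stats_frame(Y[:, 0], groups, covariates)
    data = df.drop(columns=["y"]).copy()
    ynames = []
    for j in range(Y.shape[1]):
        data[f"y{j}"] = Y[:, j]
        ynames.append(f"y{j}")
    rhs = " + ".join(["C(group)"] + cov_names) if cov_names else "C(group)"
    mv = MANOVA.from_formula(f"{' + '.join(ynames)} ~ {rhs}", data=data)
    res = mv.mv_test()
    tbl = res.results["C(group)"]["stat"]
    row = tbl.loc["Wilks' lambda"]
    return (float(row["Value"]), float(row["F Value"]),
            float(row["Num DF"]), float(row["Den DF"]),
            float(row["Pr > F"]))


def posthoc_pairwise(values, groups, covariates=None
                     ) -> dict[tuple[str, str], PairwiseComparison]:
    """Bonferroni-corrected covariate-adjusted pairwise contrasts.

    For each group pair, fits the GLM on that subset and tests the group
    indicator; raw p-values are multiplied by the number of pairs and
    capped at 1.
    """
    df, cov_names = _stats_frame(values, groups, covariates)
    levels = [lvl for lvl in df["group"].cat.categories
              if (df["group"] == lvl).any()]
    pairs = list(combinations(levels, 2))
    out: dict[tuple[str, str], PairwiseComparison] = {}
    for g1, g2 in pairs:
        sub = df[df["group"].isin([g1, g2])].copy()
        if (sub["group"] == g1).sum() < 2 or (sub["group"] == g2).sum() < 2:
            raise ValueError(f"pair {g1}-{g2} has a group smaller than 2")
        sub["ind"] = (sub["group"] == g2).astype(float)
        rhs = " + ".join(["ind"] + cov_names) if cov_names else "ind"
        fit = smf.ols(f"y ~ {rhs}", data=sub).fit()
        p_raw = float(fit.pvalues["ind"])
        out[(g1, g2)] = PairwiseComparison(
            pair=(g1, g2),
            diff=float(fit.params["ind"]),
            p_raw=p_raw,
            p_adjusted=min(1.0, len(pairs) * p_raw),
        )
    return out


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(x, y, covariates=None, x_name=None, y_name=None,
                        band: str | None = None) -> CorrelationResult:
    """Pearson correlation of residuals after removing covariates.

    An intercept is always included in the removal step, so with an empty
    covariate set this reduces to the ordinary Pearson correlation.
    The p-value uses ``t = r sqrt(df / (1 - r^2))`` with ``df = n - k - 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must align")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    Z = np.column_stack([np.ones(n), C])
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)) or \
            np.std(ry) < 1e-12 * max(1.0, np.std(y)):
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r_partial=r, p_value=p, n=n, n_covariates=k,
                             x_name=x_name, y_name=y_name, band=band)


def anova_power(effect_size_f: float, n_total: int, k_groups: int,
                alpha: float = 0.05) -> float:
    """Power of a one-way (k-group) fixed-effects ANOVA.

    Uses the noncentral F distribution with noncentrality
    ``lambda = f^2 n_total`` and degrees of freedom
    ``(k - 1, n_total - k)``; with ``f = 0`` the power equals alpha.
    """
    if effect_size_f < 0:
        raise ValueError("effect size f must be >= 0")
    df1 = k_groups - 1
    df2 = n_total - k_groups
    if df1 < 1 or df2 < 1:
        raise ValueError(f"invalid degrees of freedom ({df1}, {df2})")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    lam = effect_size_f ** 2 * n_total
    if lam == 0:  # noncentral F is undefined at nc = 0; use the central F
        return float(stats.f.sf(fcrit, df1, df2))
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def cohens_f_from_eta_sq(eta_sq: float) -> float:
    """Convert (partial) eta squared to Cohen's f: f = sqrt(e / (1 - e))."""
    if not (0 <= eta_sq < 1):
        raise ValueError("eta squared must lie in [0, 1)")
    return float(np.sqrt(eta_sq / (1.0 - eta_sq)))
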