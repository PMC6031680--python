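"""Calibration and validation experiments over the synthetic cohort.

These are the study-level analyses: they chain the generator, the
connectivity stage, the graph indices, and the covariate-adjusted
statistics, and measure operating characteristics (type-I error of the
whole chain, recovery of a planted trauma effect, recovery of a planted
partial correlation, agreement of empirical phase locking with its
analytic value).  Both the test suite and the reproduction script drive
the package through these functions.

Desk-scale problem sizes are used throughout: 15/25/15 subjects, 20
cortical nodes, 48 NoGo-like trials per subject at 250 Hz.  These keep a
hundred-replicate experiment at minutes of CPU while preserving every
qualitative property of the full-scale design (300-trial sessions, 314
nodes, 1000 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectivity import DEFAULT_BANDS, BandDefinition, cohort_connectivity
from .graph_metrics import GLOBAL_INDEX_NAMES, metrics_tables
from .group_stats import (ancova_group_test, bonferroni_threshold,
                          partial_correlation, posthoc_pairwise)
from .synthetic_data import SimConfig, cohort_to_frame, generate_cohort

#: covariates entered in every adjusted analysis (anxiety, depression, ADHD)
DEFAULT_COVARIATES = ("sai", "tai", "bdi", "caars_total")

#: 4 indices x 4 bands, the global-level test family
GLOBAL_FAMILY_SIZE = 16


def desk_scale_config(seed: int = 0, *, equal_sigma: bool = False,
                      n_trials: int = 48) -> SimConfig:
    """The reduced study conditions used for replicate experiments.

    ``equal_sigma`` removes the group effect (null cohort) while keeping
    between-subject heterogeneity.
    """
    cfg = SimConfig(
        n_subjects_per_group=(15, 25, 15),
        n_nodes=20,
        n_trials=n_trials,
        sample_rate=250.0,
        nogo_only=True,
        seed=seed,
    )
    if equal_sigma:
        s = cfg.phase_jitter_sigma[0]
        cfg = replace(cfg, phase_jitter_sigma=(s, s, s))
    return cfg


def study_config(seed: int = 0) -> "PipelineConfig":
    """The default desk-scale study: full sessions through the whole chain.

    15/25/15 subjects, 20 cortical nodes, 300-trial Go/NoGo sessions with
    the 80/20 split and realistic accuracies (so ~42-48 correct NoGo epochs
    survive selection), sensor projection through a 32-channel synthetic
    lead field and minimum-norm localization back to node space.
    """
    from .pipeline import PipelineConfig

    return PipelineConfig(
        sim=SimConfig(
            n_subjects_per_group=(15, 25, 15),
            n_nodes=20,
            n_trials=300,
            sample_rate=250.0,
            seed=seed,
        ),
        localize=True,
        n_sensors=32,
    )


def cohort_global_metrics(config: SimConfig,
                          bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and compute its global metric table.

    Returns ``(global_table, cohort_table)`` where the metric table is in
    long format (subject_id, band, index, value) and the cohort table holds
    metadata and covariates.
    """
    records, epochs = generate_cohort(config)
    cohort = cohort_to_frame(records)
    conn = cohort_connectivity(
        {r.subject_id: ep for r, ep in zip(records, epochs)}, bands=bands,
    )
    table, _ = metrics_tables(conn)
    return table, cohort


def _merged(table: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    cols = ["subject_id", "group_label", *DEFAULT_COVARIATES]
    return table.merge(cohort[cols], on="subject_id", validate="many_to_one")


def global_ancova_pvalues(table: pd.DataFrame, cohort: pd.DataFrame
                          ) -> pd.DataFrame:
    """Covariate-adjusted omnibus p-value per band x index."""
    merged = _merged(table, cohort)
    rows = []
    for (band, index), sub in merged.groupby(["band", "index"], sort=True):
        res = ancova_group_test(
            sub["value"], sub["group_label"],
            sub[list(DEFAULT_COVARIATES)], index=index, band=band,
        )
        rows.append({"band": band, "index": index, "F": res.f_stat,
                     "p": res.p_value, "partial_eta_sq": res.partial_eta_sq})
    return pd.DataFrame(rows)


@dataclass
class TypeIResult:
    """Family-wise false-positive rate of the full chain under the null."""

    n_seeds: int
    n_false_positive_runs: int
    adjusted_alpha: float

    @property
    def rate(self) -> float:
        return self.n_false_positive_runs / self.n_seeds


def null_type_one_error(n_seeds: int = 100, base_seed: int = 0,
                        alpha: float = 0.05,
                        family: int = GLOBAL_FAMILY_SIZE) -> TypeIResult:
    """Run the whole pipeline on null cohorts and count false alarms.

    Each replicate simulates a cohort with *no* group difference in phase
    jitter, runs connectivity -> metrics -> ANCOVA for all bands and
    indices, and flags the run if any test clears the Bonferroni threshold
    ``alpha / family``.  Under correct control the flagged fraction stays
    at or below ``family x threshold = alpha`` (the per-run family-wise
    level), within Monte-Carlo error.
    """
    threshold = bonferroni_threshold(alpha, family)
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)
    hits = 0
    for seed in seeds:
        cfg = desk_scale_config(int(seed), equal_sigma=True)
        table, cohort = cohort_global_metrics(cfg)
        pvals = global_ancova_pvalues(table, cohort)
        if (pvals["p"] < threshold).any():
            hits += 1
    return TypeIResult(n_seeds=n_seeds, n_false_positive_runs=hits,
                       adjusted_alpha=threshold)


@dataclass
class RecoveryResult:
    """Recovery of the planted trauma effect across replicates."""

    n_seeds: int
    n_recovered: int
    per_index_direction: dict
    mean_plv_gap: float  # mean low-minus-high subject PLV-level gap

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_seeds


def planted_effect_recovery(n_seeds: int = 50, base_seed: int = 1000,
                            alpha: float = 0.05,
                            band: str = "low_beta") -> RecoveryResult:
    """Recover the planted high-trauma coupling deficit, replicate by replicate.

    A replicate counts as recovered when, in the carrier band, every global
    index shows the planted direction in its low-vs-high contrast
    (strength, clustering, efficiency lower in the high group; path length
    higher) *and* the contrast is significant at ``alpha`` for all four
    indices.

    The contrast here is unadjusted.  The cohort's psychological covariates
    are group-correlated confounder proxies with no direct influence on the
    network metrics, so adjusting for them in this experiment would only
    inflate the contrast variance; the question asked is whether the
    planted physiological effect is detected, not whether it survives
    covariate partialling (the pipeline's statistics stage does adjust, as
    its report shows).
    """
    expected_sign = {"strength": -1, "clustering": -1, "efficiency": -1,
                     "path_length": +1}
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)
    n_recovered = 0
    direction_counts = {k: 0 for k in GLOBAL_INDEX_NAMES}
    gaps = []
    carrier_band = tuple(b for b in DEFAULT_BANDS if b.name == band)
    for seed in seeds:
        cfg = desk_scale_config(int(seed), equal_sigma=False)
        table, cohort = cohort_global_metrics(cfg, bands=carrier_band)
        merged = _merged(table, cohort)
        sub_band = merged[merged["band"] == band]
        ok = True
        for index in GLOBAL_INDEX_NAMES:
            sub = sub_band[sub_band["index"] == index]
            pw = posthoc_pairwise(sub["value"], sub["group_label"])
            comp = pw[("low", "high")]
            right_direction = np.sign(comp.diff) == expected_sign[index]
            if right_direction:
                direction_counts[index] += 1
            if not (right_direction and comp.p_raw < alpha):
                ok = False
        if ok:
            n_recovered += 1
        # PLV-level gap proxy: clustering ~ mean PLV on a complete graph
        cl = sub_band[sub_band["index"] == "clustering"]
        by_group = cl.groupby("group_label")["value"].mean()
        gaps.append(float(by_group["low"] - by_group["high"]))
    return RecoveryResult(
        n_seeds=n_seeds,
        n_recovered=n_recovered,
        per_index_direction={k: v / n_seeds
                             for k, v in direction_counts.items()},
        mean_plv_gap=float(np.mean(gaps)),
    )


def plv_recovery_errors(sigmas=(0.0, 0.25, 0.5, 1.0), n_trials: int = 2000,
                        seed: int = 0) -> pd.DataFrame:
    """Empirical vs analytic PLV for equal-jitter node pairs.

    Generates a two-node subject per jitter level and compares the measured
    carrier-band PLV with ``exp(-sigma^2)`` (both nodes at the same sigma).
    Returns a table with the Monte-Carlo standard error of the empirical
    estimate obtained from an independent resultant-length simulation.
    """
    from .connectivity import band_plv
    from .synthetic_data import expected_plv, generate_subject_epochs

    rng = np.random.default_rng(seed)
    band = BandDefinition("low_beta", 12.0, 18.0)
    rows = []
    for sigma in sigmas:
        cfg = SimConfig(n_nodes=2, n_trials=n_trials, sample_rate=250.0,
                        nogo_only=True, seed=int(rng.integers(2**31)))
        ep = generate_subject_epochs(cfg, sigma, int(rng.integers(2**31)))
        plv = float(band_plv(ep, band).weights[0, 1])
        target = expected_plv(sigma, sigma)
        # MC oracle for the sampling SE of the resultant length at this sigma
        reps = np.abs(np.mean(np.exp(
            1j * rng.normal(0.0, sigma * np.sqrt(2.0), size=(200, n_trials))
        ), axis=1))
        rows.append({"sigma": sigma, "empirical": plv, "analytic": target,
                     "abs_error": abs(plv - target),
                     "mc_se": float(reps.std(ddof=1))})
    return pd.DataFrame(rows)


def planted_partial_correlation(n: int = 150, rho: float = -0.285,
                                n_covariates: int = 3, seed: int = 0,
                                exact: bool = True):
    """Plant a partial correlation behind covariate confounding, then recover.

    Builds covariates Z, a trauma-score analog ``x`` loading on Z, and a
    nodal-clustering analog ``y`` that loads on Z *and* on the
    Z-residualized part of ``x`` with partial correlation ``rho``.  With
    ``exact=True`` the construction orthonormalizes in sample, so the
    population value is also the realized sample value and the check
    isolates estimator correctness from sampling noise.

    Returns ``(result, naive_r)`` where ``naive_r`` is the unadjusted
    Pearson correlation (confounded, hence biased away from ``rho``).
    """
    if not (-1.0 < rho < 1.0):
        raise ValueError("rho must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, n_covariates))
    design = np.column_stack([np.ones(n), Z])

    def _unit_resid(v):
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        r = v - design @ beta
        return r / np.linalg.norm(r)

    u = rng.standard_normal(n)
    e = rng.standard_normal(n)
    if exact:
        u = _unit_resid(u)
        e_r = _unit_resid(e)
        e = e_r - (e_r @ u) * u
        e /= np.linalg.norm(e)
    beta_x = rng.uniform(0.5, 1.0, size=n_covariates)
    gamma_y = rng.uniform(0.5, 1.0, size=n_covariates)
    x = Z @ beta_x + 10.0 * u  # trauma-score analog
    y = Z @ gamma_y + (rho * u + np.sqrt(1.0 - rho ** 2) * e)
    result = partial_correlation(x, y, Z, x_name="ctq_total",
                                 y_name="nodal_clustering")
    naive = float(np.corrcoef(x, y)[0, 1])
    return result, naive
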