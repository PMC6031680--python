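"""Synthetic phase-coupled cohort generator.

Generates multi-subject, multi-trial node-level signals whose pairwise
phase locking is controlled analytically, together with a subject metadata
table (childhood-trauma questionnaire scores plus anxiety / depression /
impulsivity covariates) whose group structure mirrors a quartile-split
trauma cohort.

The signal model: on trial ``k``, node ``i`` carries

    x_ik(t) = A * cos(2 pi f t + theta_k + eps_ik) + noise

with a common per-trial phase ``theta_k ~ Uniform(-pi, pi]`` and per-node
wrapped-normal phase jitter ``eps_ik ~ WN(0, sigma_i^2)``, independent over
nodes and trials.  The across-trials phase-locking value between nodes i
and j then has the closed form

    PLV_ij = E|exp(i(eps_i - eps_j))| = exp(-(sigma_i^2 + sigma_j^2) / 2),

so the generator's jitter scale ``sigma`` is an analytic dial for network
coupling: the high-trauma analog group is given a larger sigma, hence
uniformly weaker phase locking.  Wrapped-normal jitter was chosen over von
Mises precisely for this closed form.

Between-subject heterogeneity enters as a normal perturbation of sigma
around the group value, which maps onto between-subject spread of the
network indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import GO, NOGO, EpochSet, SourceEpochs

GROUP_ORDER = ("low", "middle", "high")

# Group-conditional score profiles used for covariate generation:
# (low, middle, high) means and a pooled SD per instrument.  Magnitudes
# follow the published descriptives of a 153-subject community trauma
# cohort; they are illustrative levels, not reproduction targets.  The
# essential property is the direction: anxiety / depression / ADHD scores
# increase with trauma load.
COVARIATE_PROFILES: dict[str, tuple[tuple[float, float, float], float]] = {
    "sai": ((32.45, 36.00, 41.89), 7.4),
    "tai": ((34.27, 39.17, 45.87), 9.1),
    "bdi": ((5.39, 6.92, 12.08), 5.2),
    "bis_attentional": ((15.39, 15.77, 17.66), 3.4),
    "bis_motor": ((23.91, 25.28, 26.42), 4.6),
    "bis_nonplanning": ((18.77, 17.77, 18.87), 3.8),
    "caars_inattention_memory": ((22.20, 23.92, 28.86), 6.0),
    "caars_hyperactivity_restlessness": ((16.84, 17.86, 20.79), 4.5),
    "caars_impulsivity_lability": ((17.27, 17.93, 19.47), 4.2),
    "caars_self_concept": ((14.36, 13.55, 13.95), 3.0),
    "behavioral_inhibition": ((21.34, 21.08, 21.53), 2.3),
    "bas_drive": ((9.02, 8.30, 7.79), 1.7),
    "bas_fun_seeking": ((10.57, 10.28, 10.63), 2.2),
    "bas_reward_responsiveness": ((18.14, 16.27, 16.00), 4.8),
}

# CTQ total-score profiles per group: mean, SD, and the (disjoint) truncation
# range keeping the quartile split consistent with group membership.
_CTQ_PROFILES = {
    "low": (31.41, 2.06, (25.0, 33.9)),
    "middle": (40.44, 3.61, (34.1, 47.4)),
    "high": (60.21, 10.00, (47.6, 125.0)),
}

# Dirichlet concentration used to split (total - 25) across the five
# maltreatment subscales; emotional neglect dominates in community samples.
_SUBSCALE_ALPHA = np.array([1.0, 0.9, 0.6, 1.0, 2.5])
_SUBSCALE_NAMES = (
    "ctq_physical_abuse",
    "ctq_emotional_abuse",
    "ctq_sexual_abuse",
    "ctq_physical_neglect",
    "ctq_emotional_neglect",
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the emulated study: 300 trials with an 80/20 Go/NoGo
    split at 1000 Hz, -100..900 ms epochs, three trauma groups whose phase
    jitter increases with trauma load so that the expected low-vs-high PLV
    gap is 0.03 with a between-subject PLV SD of about 0.02.
    """

    n_subjects_per_group: tuple[int, int, int] = (15, 25, 15)
    n_nodes: int = 20
    n_trials: int = 300
    go_probability: float = 0.8
    carrier_freq: float = 15.0  # Hz; sits in the low beta band (12-18 Hz)
    sample_rate: float = 1000.0
    # wrapped-normal phase jitter SD per group (low, middle, high), radians
    phase_jitter_sigma: tuple[float, float, float] = (0.90, 0.915, 0.938)
    between_subject_sigma_sd: float = 0.025  # radians
    amplitude: float = 10.0  # microvolts
    amplitude_noise_sd: float = 1.0  # microvolts
    epoch_tmin_ms: float = -100.0
    epoch_tmax_ms: float = 900.0
    go_accuracy: float = 0.94  # hit rate on Go trials
    nogo_accuracy: float = 0.88  # 1 - false-alarm rate on NoGo trials
    nogo_only: bool = False  # generate only (correct) NoGo-like trials
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_subjects_per_group):
            raise ValueError("group sizes must be positive")
        if self.n_nodes <= 0 or self.n_trials <= 0:
            raise ValueError("n_nodes and n_trials must be positive")
        if not (0.0 < self.go_probability < 1.0):
            raise ValueError("go_probability must lie in (0, 1)")
        if self.sample_rate <= 0 or self.carrier_freq <= 0:
            raise ValueError("sample_rate and carrier_freq must be positive")
        if any(s < 0 for s in self.phase_jitter_sigma):
            raise ValueError("phase jitter sigma must be >= 0")
        if self.between_subject_sigma_sd < 0 or self.amplitude_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.epoch_tmax_ms <= self.epoch_tmin_ms:
            raise ValueError("epoch window is empty")
        for p in (self.go_accuracy, self.nogo_accuracy):
            if not (0.0 <= p <= 1.0):
                raise ValueError("accuracies must lie in [0, 1]")

    @property
    def n_epoch_samples(self) -> int:
        return int(round((self.epoch_tmax_ms - self.epoch_tmin_ms)
                         * self.sample_rate / 1000.0))


@dataclass
class SubjectRecord:
    """Per-subject metadata: trauma scores, covariates, group label."""

    subject_id: str
    group_label: str
    ctq_total: float
    ctq_physical_abuse: float
    ctq_emotional_abuse: float
    ctq_sexual_abuse: float
    ctq_physical_neglect: float
    ctq_emotional_neglect: float
    sai: float
    tai: float
    bdi: float
    bis_total: float
    bis_attentional: float
    bis_motor: float
    bis_nonplanning: float
    caars_total: float
    caars_inattention_memory: float
    caars_hyperactivity_restlessness: float
    caars_impulsivity_lability: float
    caars_self_concept: float
    behavioral_inhibition: float
    behavioral_activation: float
    bas_drive: float
    bas_fun_seeking: float
    bas_reward_responsiveness: float
    sigma: float  # generative per-subject phase-jitter SD (ground truth)


def expected_plv(sigma_i, sigma_j):
    """Analytic across-trials PLV for wrapped-normal phase jitter.

    ``E|exp(i(eps_i - eps_j))| = exp(-(sigma_i^2 + sigma_j^2)/2)`` since the
    phase difference of two independent WN(0, s^2) variables is
    WN(0, sigma_i^2 + sigma_j^2) and the mean resultant length of
    WN(0, v) is exp(-v/2).
    """
    si = np.asarray(sigma_i, dtype=float)
    sj = np.asarray(sigma_j, dtype=float)
    if np.any(si < 0) or np.any(sj < 0):
        raise ValueError("sigma must be >= 0")
    out = np.exp(-(si ** 2 + sj ** 2) / 2.0)
    return float(out) if out.ndim == 0 else out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_conditions(config: SimConfig, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    if config.nogo_only:
        conds = np.full(config.n_trials, NOGO, dtype=object)
        correct = np.ones(config.n_trials, dtype=bool)
        return conds, correct
    is_go = rng.random(config.n_trials) < config.go_probability
    conds = np.where(is_go, GO, NOGO).astype(object)
    acc = np.where(is_go, config.go_accuracy, config.nogo_accuracy)
    correct = rng.random(config.n_trials) < acc
    return conds, correct


def generate_subject_epochs(config: SimConfig, subject_sigma, seed,
                            noise_correlation: np.ndarray | None = None
                            ) -> SourceEpochs:
    """Generate one subject's trial tensor (trials x nodes x samples).

    ``subject_sigma`` is a scalar or per-node vector of wrapped-normal phase
    jitter SDs in radians.  ``noise_correlation`` optionally supplies a
    node-by-node correlation matrix for the phase jitter (per-edge coupling
    mode; the independent default keeps the closed-form expected PLV).
    """
    rng = _as_rng(seed)
    n_samples = config.n_epoch_samples
    if n_samples <= 0:
        raise ValueError("epoch window contains no samples")
    sigma = np.broadcast_to(
        np.asarray(subject_sigma, dtype=float), (config.n_nodes,)
    ).copy()
    if not np.all(np.isfinite(sigma)) or np.any(sigma < 0):
        raise ValueError("subject sigma must be finite and >= 0")

    t = (config.epoch_tmin_ms / 1000.0
         + np.arange(n_samples) / config.sample_rate)
    theta = rng.uniform(-np.pi, np.pi, size=config.n_trials)  # common drive
    if noise_correlation is None:
        eps = rng.standard_normal((config.n_trials, config.n_nodes)) * sigma
    else:
        R = np.asarray(noise_correlation, dtype=float)
        if R.shape != (config.n_nodes, config.n_nodes):
            raise ValueError("noise_correlation must be n_nodes x n_nodes")
        cov = R * np.outer(sigma, sigma)
        eps = rng.multivariate_normal(
            np.zeros(config.n_nodes), cov, size=config.n_trials,
            method="cholesky",
        )

    phase = (2.0 * np.pi * config.carrier_freq * t)[None, None, :] \
        + theta[:, None, None] + eps[:, :, None]
    data = config.amplitude * np.cos(phase)
    if config.amplitude_noise_sd > 0:
        data += config.amplitude_noise_sd * rng.standard_normal(data.shape)

    conds, correct = _draw_conditions(config, rng)
    return EpochSet(
        data=data,
        sample_rate=config.sample_rate,
        tmin_ms=config.epoch_tmin_ms,
        conditions=conds,
        correct=correct,
    )


def _draw_ctq_total(group: str, rng: np.random.Generator) -> float:
    mean, sd, (lo, hi) = _CTQ_PROFILES[group]
    # rejection-sample the truncated normal; ranges are several SDs wide
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _split_subscales(total: float, rng: np.random.Generator) -> np.ndarray:
    """Split a CTQ total into 5 subscale scores, each within [5, 25]."""
    excess = total - 25.0  # each subscale has a floor of 5
    shares = rng.dirichlet(_SUBSCALE_ALPHA) * excess
    sub = 5.0 + shares
    # waterfill any overflow above the per-subscale cap of 25
    for _ in range(10):
        over = np.clip(sub - 25.0, 0.0, None)
        if not over.any():
            break
        sub = np.minimum(sub, 25.0)
        room = 25.0 - sub
        if room.sum() <= 0:
            break
        sub = sub + over.sum() * room / room.sum()
    return np.clip(sub, 5.0, 25.0)


def generate_cohort(config: SimConfig
                    ) -> tuple[list[SubjectRecord], list[SourceEpochs]]:
    """Generate the full synthetic cohort: metadata plus signal tensors.

    Trauma-questionnaire totals are drawn from disjoint group ranges so the
    quartile split recovers the generative groups; per-subject phase jitter
    is drawn around the group sigma; covariates follow group-graded means.
    Fully reproducible under a fixed ``config.seed``.
    """
    config.validate()
    if any(n < 2 for n in config.n_subjects_per_group):
        raise ValueError("each group needs >= 2 subjects for statistics")
    # local import: group assignment is owned by the statistics module
    from .group_stats import assign_groups

    root = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])

    groups = [g for g, n in zip(GROUP_ORDER, config.n_subjects_per_group)
              for _ in range(n)]
    n_total = len(groups)
    sigma_by_group = dict(zip(GROUP_ORDER, config.phase_jitter_sigma))

    records: list[SubjectRecord] = []
    epochs: list[SourceEpochs] = []
    ctq_totals = np.empty(n_total)
    signal_seeds = root.spawn(n_total + 1)[1:]

    for idx, group in enumerate(groups):
        ctq_totals[idx] = _draw_ctq_total(group, meta_rng)
        sub = _split_subscales(ctq_totals[idx], meta_rng)
        sigma_s = max(
            0.0,
            meta_rng.normal(sigma_by_group[group],
                            config.between_subject_sigma_sd),
        )
        gi = GROUP_ORDER.index(group)
        scores = {
            name: float(meta_rng.normal(means[gi], sd))
            for name, (means, sd) in COVARIATE_PROFILES.items()
        }
        rec = SubjectRecord(
            subject_id=f"sub-{idx:03d}",
            group_label=group,  # provisional; reset from quartiles below
            ctq_total=float(ctq_totals[idx]),
            **dict(zip(_SUBSCALE_NAMES, sub.astype(float))),
            sai=scores["sai"],
            tai=scores["tai"],
            bdi=scores["bdi"],
            bis_total=(scores["bis_attentional"] + scores["bis_motor"]
                       + scores["bis_nonplanning"]),
            bis_attentional=scores["bis_attentional"],
            bis_motor=scores["bis_motor"],
            bis_nonplanning=scores["bis_nonplanning"],
            caars_total=(scores["caars_inattention_memory"]
                         + scores["caars_hyperactivity_restlessness"]
                         + scores["caars_impulsivity_lability"]
                         + scores["caars_self_concept"]),
            caars_inattention_memory=scores["caars_inattention_memory"],
            caars_hyperactivity_restlessness=scores[
                "caars_hyperactivity_restlessness"],
            caars_impulsivity_lability=scores["caars_impulsivity_lability"],
            caars_self_concept=scores["caars_self_concept"],
            behavioral_inhibition=scores["behavioral_inhibition"],
            behavioral_activation=(scores["bas_drive"]
                                   + scores["bas_fun_seeking"]
                                   + scores["bas_reward_responsiveness"]),
            bas_drive=scores["bas_drive"],
            bas_fun_seeking=scores["bas_fun_seeking"],
            bas_reward_responsiveness=scores["bas_reward_responsiveness"],
            sigma=float(sigma_s),
        )
        records.append(rec)
        epochs.append(
            generate_subject_epochs(
                config, sigma_s, np.random.default_rng(signal_seeds[idx])
            )
        )

    labels = assign_groups(ctq_totals)
    for rec, label in zip(records, labels):
        rec.group_label = str(label)
    return records, epochs


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subject metadata as a tidy table (one row per subject)."""
    return pd.DataFrame([asdict(r) for r in records])


def project_to_sensors(source: SourceEpochs, gain: np.ndarray,
                       sensor_noise_sd: float = 0.0,
                       seed=None) -> EpochSet:
    """Forward-project node epochs to sensors: ``y = G x + noise``."""
    G = getattr(gain, "matrix", gain)
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] != source.n_channels:
        raise ValueError(
            f"gain columns ({G.shape[-1] if G.ndim == 2 else '?'}) must match "
            f"node count ({source.n_channels})"
        )
    rng = _as_rng(seed)
    data = np.einsum("mn,tns->tms", G, source.data)
    if sensor_noise_sd > 0:
        data = data + rng.normal(0.0, sensor_noise_sd, size=data.shape)
    return EpochSet(
        data=data,
        sample_rate=source.sample_rate,
        tmin_ms=source.tmin_ms,
        conditions=source.conditions.copy(),
        correct=source.correct.copy(),
    )
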