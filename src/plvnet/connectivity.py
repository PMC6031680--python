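"""Band-limited instantaneous phase and phase-locking-value adjacency.

The phase-locking value between nodes i and j is computed in the
across-trials convention standard for event-locked data:

    PLV_ij(t) = | (1/N) sum_k exp(i (phi_ik(t) - phi_jk(t))) |

averaged over the samples of the analysis window (200-700 ms after the
NoGo stimulus by default, the late positive component's latency range).
A within-trial-over-time mode is available behind a flag because the
averaging order is a convention, not a theorem.

Band filtering for phase extraction reuses the pipeline's zero-phase
filter applied to the *whole* epoch before cropping to the window, so
filter and Hilbert edge transients fall outside the analyzed interval.
Delta and theta are excluded from the default band set: the 500 ms window
holds only one or two full cycles of those rhythms, which biases
phase-locking estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .preprocess import NOGO, EpochSet, bandpass_filter, select_condition

logger = logging.getLogger(__name__)

DEFAULT_PLV_WINDOW_MS = (200.0, 700.0)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges for {self.name!r}")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("low_beta", 12.0, 18.0),
    BandDefinition("high_beta", 18.0, 30.0),
    BandDefinition("gamma", 30.0, 55.0),
)


@dataclass
class PhaseEpochs:
    """Instantaneous phases, trials x nodes x window samples, in (-pi, pi]."""

    phases: np.ndarray
    sample_rate: float
    window_ms: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric, zero-diagonal PLV adjacency with provenance tags."""

    weights: np.ndarray
    band: str | None = None
    subject_id: str | None = None
    n_trials: int | None = None
    window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        if W.min() < 0 or W.max() > 1:
            raise ValueError("PLV weights must lie in [0, 1]")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def instantaneous_phase(epochs: EpochSet,
                        window_ms: tuple[float, float] = DEFAULT_PLV_WINDOW_MS
                        ) -> PhaseEpochs:
    """Analytic-signal phase of band-limited epochs, cropped to the window.

    The Hilbert transform runs over the full epoch; only afterwards are the
    phases cropped to ``window_ms`` (half-open), which keeps edge
    transients out of the analyzed interval.
    """
    if epochs.n_trials == 0:
        raise ValueError("no epochs")
    flat = np.abs(epochs.data).max(axis=2) == 0
    if flat.any():
        raise ValueError(
            "instantaneous phase undefined for identically zero signal "
            f"(first offending trial/node: {np.argwhere(flat)[0].tolist()})"
        )
    lo, hi = window_ms
    times = epochs.times_ms
    mask = (times >= lo) & (times < hi)
    if not mask.any():
        raise ValueError(
            f"window {window_ms} ms outside epoch span "
            f"[{epochs.tmin_ms}, {epochs.tmax_ms}) ms"
        )
    analytic = hilbert(epochs.data, axis=-1)
    phases = np.angle(analytic[..., mask])
    return PhaseEpochs(phases=phases, sample_rate=epochs.sample_rate,
                       window_ms=(float(lo), float(hi)))


def plv_matrix(phases: PhaseEpochs, band: str | None = None,
               subject_id: str | None = None,
               convention: str = "across_trials") -> ConnectivityMatrix:
    """Phase-locking-value adjacency from a phase tensor.

    ``convention='across_trials'`` (default): resultant over trials at each
    window sample, then averaged over samples.  ``'within_trial'``:
    resultant over window samples within each trial, then averaged over
    trials.  The across-trials form needs at least two trials; with a
    single trial it is identically one and therefore meaningless.
    """
    P = phases.phases
    n_trials, n_nodes, n_t = P.shape
    if n_t == 0:
        raise ValueError("empty analysis window")
    if convention == "across_trials" and n_trials < 2:
        raise ValueError(
            "across-trials PLV needs >= 2 trials (a single trial always "
            "gives PLV=1); pool more epochs or use convention='within_trial'"
        )
    Z = np.exp(1j * P)
    return _plv_from_unit(Z, n_trials, band=band, subject_id=subject_id,
                          convention=convention, window_ms=phases.window_ms)


def _plv_from_unit(Z: np.ndarray, n_trials: int, *, band, subject_id,
                   convention: str, window_ms) -> ConnectivityMatrix:
    n_nodes, n_t = Z.shape[1], Z.shape[2]
    if convention == "across_trials":
        # R[t, n, m] = |(1/K) sum_k z_nk(t) conj(z_mk(t))|, then mean over t;
        # batched BLAS over time chunks bounds the n_nodes^2 workspace
        acc = np.zeros((n_nodes, n_nodes))
        chunk = max(1, int(4e6 // (n_nodes * n_nodes)))
        for t0 in range(0, n_t, chunk):
            Zt = np.ascontiguousarray(Z[:, :, t0:t0 + chunk].transpose(2, 1, 0))
            cross = Zt @ Zt.conj().transpose(0, 2, 1) / n_trials
            acc += np.abs(cross).sum(axis=0)
        W = acc / n_t
    elif convention == "within_trial":
        cross = np.einsum("knt,kmt->knm", Z, Z.conj()) / n_t
        W = np.abs(cross).mean(axis=0)
    else:
        raise ValueError(f"unknown PLV convention {convention!r}")

    W = np.clip((W + W.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return ConnectivityMatrix(
        weights=W, band=band, subject_id=subject_id, n_trials=n_trials,
        window_ms=window_ms,
    )


def band_plv(epochs: EpochSet, band: BandDefinition,
             window_ms: tuple[float, float] = DEFAULT_PLV_WINDOW_MS,
             subject_id: str | None = None,
             convention: str = "across_trials") -> ConnectivityMatrix:
    """Filter to one band, extract phases, and build the PLV matrix.

    Equivalent to ``plv_matrix(instantaneous_phase(bandpass_filter(...)))``
    but works on the normalized analytic signal directly, skipping the
    angle/exponential round trip.
    """
    filtered = bandpass_filter(epochs, band.f_lo, band.f_hi)
    if filtered.n_trials == 0:
        raise ValueError("no epochs")
    if convention == "across_trials" and filtered.n_trials < 2:
        raise ValueError(
            "across-trials PLV needs >= 2 trials (a single trial always "
            "gives PLV=1); pool more epochs or use convention='within_trial'"
        )
    flat = np.abs(filtered.data).max(axis=2) == 0
    if flat.any():
        raise ValueError("instantaneous phase undefined for zero signal")
    lo, hi = window_ms
    times = filtered.times_ms
    mask = (times >= lo) & (times < hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms outside epoch span")
    analytic = hilbert(filtered.data, axis=-1)[..., mask]
    mag = np.abs(analytic)
    Z = analytic / np.where(mag > 0, mag, 1.0)
    return _plv_from_unit(Z, filtered.n_trials, band=band.name,
                          subject_id=subject_id, convention=convention,
                          window_ms=(float(lo), float(hi)))


def cohort_connectivity(subject_epochs: Mapping[str, EpochSet],
                        bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                        window_ms: tuple[float, float] = DEFAULT_PLV_WINDOW_MS,
                        condition: str | None = NOGO,
                        correct_only: bool = True,
                        convention: str = "across_trials"
                        ) -> dict[str, dict[str, ConnectivityMatrix]]:
    """Per-subject, per-band PLV matrices for a cohort.

    ``condition`` selects usable epochs first (pass ``None`` if selection
    already happened upstream).  Subjects with fewer than two usable epochs
    are dropped with a logged warning.
    """
    node_counts = {ep.n_channels for ep in subject_epochs.values()}
    if len(node_counts) > 1:
        raise ValueError(f"subjects disagree on node count: {node_counts}")

    out: dict[str, dict[str, ConnectivityMatrix]] = {}
    for sid, epochs in subject_epochs.items():
        if condition is not None:
            try:
                epochs = select_condition(epochs, condition=condition,
                                          correct_only=correct_only)
            except ValueError:
                logger.warning("subject %s: no usable %s epochs; dropped",
                               sid, condition)
                continue
        if epochs.n_trials < 2:
            logger.warning(
                "subject %s: %d usable epoch(s) < 2; dropped",
                sid, epochs.n_trials,
            )
            continue
        out[sid] = {
            band.name: band_plv(epochs, band, window_ms=window_ms,
                                subject_id=sid, convention=convention)
            for band in bands
        }
    return out


def save_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Write a PLV matrix as delimited text that round-trips bit-exactly."""
    np.savetxt(path, matrix.weights, delimiter=",", fmt="%.17g")


def load_matrix(path: str | Path, band: str | None = None,
                subject_id: str | None = None) -> ConnectivityMatrix:
    W = np.loadtxt(path, delimiter=",", ndmin=2)
    return ConnectivityMatrix(weights=W, band=band, subject_id=subject_id)


def connectivity_index(conn: Mapping[str, Mapping[str, ConnectivityMatrix]]
                       ) -> pd.DataFrame:
    """Provenance table: one row per stored subject x band matrix."""
    rows = []
    for sid, per_band in conn.items():
        for band, m in per_band.items():
            rows.append({
                "subject_id": sid, "band": band, "n_nodes": m.n_nodes,
                "n_trials": m.n_trials,
                "window_lo_ms": None if m.window_ms is None else m.window_ms[0],
                "window_hi_ms": None if m.window_ms is None else m.window_ms[1],
            })
    return pd.DataFrame(rows)
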