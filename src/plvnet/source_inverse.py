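"""Minimum-norm source estimation on a synthetic forward model.

Maps sensor-space epochs to cortical node time series with the classic
L2 minimum-norm inverse

    W = G^T (G G^T + lambda^2 I)^(-1),

where ``G`` is the lead-field (gain) matrix and ``lambda`` a Tikhonov
regularization parameter.  The anatomical head model of a real study cannot
be rebuilt without its template assets, so the forward model here is
synthetic: dipoles with fixed random orientations on a unit sphere, sensors
on a surrounding shell, and an inverse-square dipole kernel.  Node reduction
("as evenly as possible") is deterministic farthest-point sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import EpochSet, SourceEpochs


@dataclass
class GainMatrix:
    """Forward operator: sensors x sources, plus 3-D source positions."""

    matrix: np.ndarray
    source_coordinates: np.ndarray  # sources x 3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.source_coordinates = np.asarray(self.source_coordinates,
                                             dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("gain must be sensors x sources")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("gain contains non-finite entries")
        if self.source_coordinates.shape != (self.matrix.shape[1], 3):
            raise ValueError("source_coordinates must be sources x 3")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


@dataclass
class InverseOperator:
    """Regularized minimum-norm inverse: sources x sensors."""

    matrix: np.ndarray
    lam: float


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic, nearly uniform points on a sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return radius * pts


def make_synthetic_gain(n_sensors: int, n_sources: int, seed: int = 0,
                        sensor_radius: float = 1.3) -> GainMatrix:
    """Build a smooth synthetic lead field.

    Sources sit on the unit sphere with seeded random fixed orientations;
    sensors on an outer shell.  Entry (m, s) is the field of a unit dipole,
    ``o_s . (r_m - p_s) / |r_m - p_s|^3``, column-normalized so each source
    projects with unit sensor-space norm.
    """
    if n_sensors < 1 or n_sources < 1:
        raise ValueError("need at least one sensor and one source")
    rng = np.random.default_rng(seed)
    sources = fibonacci_sphere(n_sources, radius=1.0)
    sensors = fibonacci_sphere(n_sensors, radius=sensor_radius)
    orient = rng.standard_normal((n_sources, 3))
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)

    diff = sensors[:, None, :] - sources[None, :, :]  # m x s x 3
    dist3 = np.linalg.norm(diff, axis=2) ** 3
    G = np.einsum("msd,sd->ms", diff, orient) / dist3
    G /= np.linalg.norm(G, axis=0, keepdims=True)
    return GainMatrix(matrix=G, source_coordinates=sources)


def default_lambda(gain: GainMatrix | np.ndarray, snr: float = 3.0) -> float:
    """Regularization scaled to the gain: lambda^2 = tr(GG^T)/(m * SNR^2)."""
    G = getattr(gain, "matrix", gain)
    G = np.asarray(G, dtype=float)
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(np.sqrt(np.einsum("ms,ms->", G, G) / (G.shape[0] * snr ** 2)))


def minimum_norm_inverse(gain: GainMatrix | np.ndarray, lam: float
                         ) -> InverseOperator:
    """Construct ``W = G^T (G G^T + lambda^2 I)^(-1)``.

    For ``lam == 0`` and full-row-rank ``G`` this is the Moore-Penrose
    pseudo-inverse; a singular system at ``lam == 0`` raises.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    G = getattr(gain, "matrix", gain)
    G = np.asarray(G, dtype=float)
    A = G @ G.T + (lam ** 2) * np.eye(G.shape[0])
    try:
        # solve(A, G) = A^-1 G; its transpose is G^T A^-1 since A = A^T
        W = np.linalg.solve(A, G).T
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "sensor covariance G G^T + lambda^2 I is singular; "
            "use lambda > 0 or a full-row-rank gain"
        ) from exc
    return InverseOperator(matrix=W, lam=float(lam))


def apply_inverse(epochs: EpochSet, inv: InverseOperator) -> SourceEpochs:
    """Per-trial node time series: ``x_hat = W y``."""
    W = np.asarray(inv.matrix, dtype=float)
    if W.shape[1] != epochs.n_channels:
        raise ValueError(
            f"inverse expects {W.shape[1]} sensors, epochs have "
            f"{epochs.n_channels}"
        )
    data = np.einsum("nm,tms->tns", W, epochs.data)
    return replace(epochs, data=data, channel_labels=None)


def downsample_nodes(source_coordinates: np.ndarray, n_nodes: int
                     ) -> np.ndarray:
    """Pick ``n_nodes`` sources spread as evenly as possible.

    Greedy farthest-point sampling seeded by the source nearest the
    centroid: the seed initializes the distance field (so the first pick is
    the source farthest from the center), and each subsequent pick maximizes
    the minimum distance to the already chosen set.  Ties break to the
    lowest index, so the result is deterministic given the coordinates.
    """
    coords = np.asarray(source_coordinates, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coordinates must be points x dims")
    n = coords.shape[0]
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if n_nodes > n:
        raise ValueError(f"cannot select {n_nodes} nodes from {n} sources")

    centroid = coords.mean(axis=0)
    anchor = int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))
    chosen: list[int] = []
    min_dist = np.linalg.norm(coords - coords[anchor], axis=1)
    for _ in range(n_nodes):
        min_dist[chosen] = -np.inf
        nxt = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        chosen.append(nxt)
        min_dist = np.minimum(min_dist,
                              np.linalg.norm(coords - coords[nxt], axis=1))
    return np.asarray(chosen, dtype=int)
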