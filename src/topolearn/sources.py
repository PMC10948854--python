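"""sLORETA source estimation of covariance-map generators.

Given a scalp map phi (here: a covariance map, treated as an instantaneous
field) and a leadfield K (channels x 3*points, average-referenced), the
minimum-norm estimate is

    j_hat = K^T (K K^T + lambda H)^+ phi,

with H the common-average-reference centering matrix, and sLORETA
standardizes each source point's 3-vector by the corresponding 3x3
diagonal block of the resolution matrix R = K^T (K K^T + lambda H)^+ K:

    power_v = j_hat_v^T  (R_vv)^-1  j_hat_v .

This standardization gives exact localization of single noiseless point
sources at lambda = 0. Powers are non-negative and scale quadratically
with the input map; the peak location is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import pinvh

from .forward import Leadfield
from .topostats import CovarianceMap


@dataclass
class SourceEstimate:
    """Per-source-point standardized power with peak bookkeeping."""

    power: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    regularization: float
    skipped: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if (self.power[np.isfinite(self.power)] < -1e-10).any():
            raise ValueError("sLORETA power must be non-negative")
        self.power = np.clip(self.power, 0.0, None)

    @property
    def peak_index(self) -> int:
        return int(np.nanargmax(self.power))

    @property
    def peak_position(self) -> np.ndarray:
        return self.positions[self.peak_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "power": self.power,
            }
        )


def default_lambda(K: np.ndarray, scale: float = 0.05) -> float:
    """Regularization scaled to the gain matrix: scale * trace(K K^T)/n_ch."""
    return float(scale * np.einsum("ij,ij->", K, K) / K.shape[0])


class SloretaOperator:
    """Precomputed sLORETA transform for one leadfield and regularization.

    Building the operator factors out the pseudo-inverse and the per-point
    3x3 standardization blocks so that many maps can be inverted cheaply.
    """

    def __init__(self, lf: Leadfield, lam: float | str = 0.0):
        n_ch = lf.n_channels
        K = lf.matrix()  # (n_ch, 3P)
        # enforce common-average reference of the gains
        K = K - K.mean(axis=0, keepdims=True)
        if lam == "auto":
            lam = default_lambda(K)
        lam = float(lam)
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        H = np.eye(n_ch) - np.full((n_ch, n_ch), 1.0 / n_ch)
        Minv = pinvh(K @ K.T + lam * H)
        self.lam = lam
        self.lf = lf
        self._T = K.T @ Minv  # (3P, n_ch)
        R = self._T @ K  # resolution matrix (3P, 3P); need diag blocks only
        P = lf.n_points
        self._blocks_inv = np.empty((P, 3, 3))
        self._skipped = np.zeros(P, dtype=bool)
        for v in range(P):
            blk = R[3 * v : 3 * v + 3, 3 * v : 3 * v + 3]
            # pinvh tolerates the rank deficiency induced by the average
            # reference; a numerically zero block is flagged and skipped
            if np.linalg.norm(blk) < 1e-14:
                self._skipped[v] = True
                self._blocks_inv[v] = 0.0
            else:
                self._blocks_inv[v] = pinvh(blk)

    def apply(self, scalp_map: np.ndarray) -> SourceEstimate:
        phi = np.asarray(scalp_map, dtype=float)
        if phi.shape != (self.lf.n_channels,):
            raise ValueError("map does not match leadfield channels")
        phi = phi - phi.mean()
        j = (self._T @ phi).reshape(self.lf.n_points, 3)
        power = np.einsum("vi,vij,vj->v", j, self._blocks_inv, j)
        power[self._skipped] = np.nan
        return SourceEstimate(
            power=power,
            positions=self.lf.positions,
            regularization=self.lam,
            skipped=self._skipped if self._skipped.any() else None,
        )


def sloreta(
    cov_map: CovarianceMap | np.ndarray, lf: Leadfield, lam: float | str = 0.0
) -> SourceEstimate:
    """Standardized minimum-norm (sLORETA) inversion of one scalp map."""
    values = cov_map.values if isinstance(cov_map, CovarianceMap) else cov_map
    return SloretaOperator(lf, lam).apply(values)


def _grid_neighbors(positions: np.ndarray, radius: float) -> list[np.ndarray]:
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    r2 = radius**2
    return [np.flatnonzero((row <= r2) & (row > 0)) for row in d2]


def local_maxima(est: SourceEstimate, neighbor_radius: float) -> np.ndarray:
    """Indices of strict local maxima of the power over the source grid,
    sorted by descending power."""
    nbrs = _grid_neighbors(est.positions, neighbor_radius)
    idx = [
        v
        for v in range(len(est.power))
        if np.isfinite(est.power[v])
        and (est.power[v] > est.power[nbrs[v]]).all()
    ]
    idx = np.asarray(idx, dtype=int)
    return idx[np.argsort(est.power[idx])[::-1]]


def localize_window(
    cov_map: CovarianceMap,
    lf: Leadfield,
    lam: float | str = 0.0,
    top_k: int = 5,
    neighbor_radius: float | None = None,
) -> tuple[SourceEstimate, pd.DataFrame]:
    """Invert a window-averaged covariance map and rank its local maxima.

    Returns the estimate plus a table of up to ``top_k`` local maxima with
    coordinates and standardized power, strongest first.
    """
    est = sloreta(cov_map, lf, lam)
    if neighbor_radius is None:
        # slightly above the smallest grid step so the 6-neighborhood is used
        step = float(np.diff(np.unique(np.round(lf.positions[:, 2], 9))).min())
        neighbor_radius = 1.5 * step
    peaks = local_maxima(est, neighbor_radius)[:top_k]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(peaks) + 1),
            "x": est.positions[peaks, 0],
            "y": est.positions[peaks, 1],
            "z": est.positions[peaks, 2],
            "power": est.power[peaks],
        }
    )
    return est, table
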