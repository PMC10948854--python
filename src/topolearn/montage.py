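"""Electrode montages on the unit sphere.

All spatial operations downstream (noise smoothing, channel interpolation,
forward modelling) work with electrode positions normalized to the unit
sphere, so the montage is stored that way: labels plus unit 3-vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Montage:
    """Electrode labels and unit-sphere positions.

    Parameters
    ----------
    names : list of str
        Channel labels (10-20 style, e.g. ``"Oz"``).
    positions : ndarray, shape (n_channels, 3)
        Cartesian positions on the unit sphere (x: right, y: anterior,
        z: superior).
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if len(self.names) != pos.shape[0]:
            raise ValueError("number of names and positions differ")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def great_circle_distances(self) -> np.ndarray:
        """Pairwise angular distances (radians) between electrodes."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cosang)


def unit_sphere_projection(xyz: np.ndarray) -> np.ndarray:
    """Center a cloud of electrode positions on its best-fit sphere center
    and project radially onto the unit sphere."""
    xyz = np.asarray(xyz, dtype=float)
    center = _fit_sphere_center(xyz)
    rel = xyz - center
    return rel / np.linalg.norm(rel, axis=1, keepdims=True)


def _fit_sphere_center(xyz: np.ndarray) -> np.ndarray:
    # linear least squares for |p - c|^2 = r^2  <=>  2 p.c + (r^2 - |c|^2) = |p|^2
    A = np.column_stack([2.0 * xyz, np.ones(len(xyz))])
    b = np.sum(xyz**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def biosemi64() -> Montage:
    """The 64-channel Biosemi 10-20 layout, projected to the unit sphere.

    Positions come from the standard montage shipped with MNE-Python.
    """
    import mne

    m = mne.channels.make_standard_montage("biosemi64")
    ch_pos = m.get_positions()["ch_pos"]
    names = list(ch_pos)
    xyz = np.array([ch_pos[n] for n in names])
    return Montage(tuple(names), unit_sphere_projection(xyz))


def save_montage(montage: Montage, path) -> None:
    """Write ``label x y z`` rows, one electrode per line."""
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(montage.names, montage.positions):
            fh.write(f"{name}\t{x:.8f}\t{y:.8f}\t{z:.8f}\n")


def load_montage(path) -> Montage:
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return Montage(tuple(names), np.asarray(rows))
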