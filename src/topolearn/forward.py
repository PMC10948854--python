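"""EEG forward modelling in a concentric-sphere head.

The head is modelled as nested homogeneous conducting shells (default
three: brain, skull, scalp). For a current dipole inside the innermost
shell the scalp potential has the classical Legendre series solution: per
spherical-harmonic degree n the radial profile in each shell is
``A r^n + B r^-(n+1)``, with the dipole contributing a source term
``s_n r^-(n+1)`` in the innermost shell, and the coefficients fixed by
continuity of potential and radial current at each interface plus a
no-outflow condition at the scalp surface. Solving that small linear
system per degree yields a per-degree transfer factor; the scalp
potential of a dipole with moment q at position p (eccentricity b = |p|)
and an electrode in unit direction e is then

    V(e) = sum_n  c_n * b^(n-1) / (4 pi sigma_1)
           * [ n (q . p_hat) P_n(x)  +  (q_t . e_perp) P_n'(x) ],

with x = e . p_hat, q_t the tangential part of the moment, and e_perp the
projection of e onto the tangent plane at the dipole. For equal shell
conductivities this reduces to the homogeneous-sphere solution (e.g. a
central dipole gives V = 3 q cos(theta) / (4 pi sigma R^2)), which serves
as a closed-form check.

Leadfields are returned average-referenced: for scalp maps that are
themselves average-referenced, the reference of the gains is immaterial,
and the zero-mean convention matches the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .montage import Montage

#: shell radii relative to the scalp radius and conductivities (S/m-like
#: relative units) for brain, skull, scalp; skull:brain ratio 1:80.
DEFAULT_RADII = (0.87, 0.92, 1.0)
DEFAULT_SIGMAS = (1.0, 0.0125, 1.0)

#: sources must stay strictly inside the innermost (brain) shell
DEFAULT_BRAIN_FILL = 0.92  # max source radius as a fraction of brain radius


@dataclass
class Leadfield:
    """Forward gains for three orthogonal unit dipoles per source point.

    Attributes
    ----------
    gains : ndarray, shape (n_points, 3, n_channels)
        Average-referenced scalp potentials for unit x/y/z dipole moments.
    positions : ndarray, shape (n_points, 3)
        Source positions (same length unit as the montage sphere).
    ch_names : tuple of str
    """

    gains: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    ch_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.gains.ndim != 3 or self.gains.shape[1] != 3:
            raise ValueError("gains must be (n_points, 3, n_channels)")
        if self.positions.shape != (self.gains.shape[0], 3):
            raise ValueError("positions do not match gains")
        if len(self.ch_names) != self.gains.shape[2]:
            raise ValueError("channel labels do not match gains")
        if not np.isfinite(self.gains).all():
            raise ValueError("non-finite gains")
        self.ch_names = tuple(self.ch_names)

    @property
    def n_points(self) -> int:
        return self.gains.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gains.shape[2]

    def matrix(self) -> np.ndarray:
        """Gains as ``(n_channels, 3 * n_points)`` with orientation fastest."""
        return self.gains.transpose(2, 0, 1).reshape(self.n_channels, -1)


class ShellModel:
    """Per-degree transfer factors of the layered-sphere forward problem."""

    def __init__(
        self,
        radii=DEFAULT_RADII,
        sigmas=DEFAULT_SIGMAS,
        n_degrees: int = 160,
    ):
        radii = tuple(float(r) for r in radii)
        sigmas = tuple(float(s) for s in sigmas)
        if len(radii) != len(sigmas):
            raise ValueError("radii and sigmas differ in length")
        if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly increasing")
        if min(sigmas) <= 0:
            raise ValueError("conductivities must be positive")
        self.radii = radii
        self.sigmas = sigmas
        self.n_degrees = int(n_degrees)
        # solve on radii normalized to the scalp radius: r^n / r^-(n+1)
        # terms stay well-scaled for any physical unit of length
        self._nradii = tuple(r / radii[-1] for r in radii)
        self._transfer = self._solve_transfer()

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]

    def _solve_transfer(self) -> np.ndarray:
        """Scalp-surface coefficient per unit dipole source coefficient.

        For each degree n, unknowns are A_1 and (A_i, B_i) for the outer
        shells (B_1 = 0 keeps the solution regular together with the
        explicit source term). Returns c[n] such that the scalp potential
        coefficient equals c[n] * s_n for a source term s_n r^-(n+1) in
        shell 1.
        """
        L = len(self._nradii)
        R = 1.0
        c = np.zeros(self.n_degrees + 1)
        for n in range(1, self.n_degrees + 1):
            m = 2 * L - 1
            A = np.zeros((m, m))
            rhs = np.zeros(m)
            # unknown order: A_1, A_2, B_2, ..., A_L, B_L
            def col_A(i):  # shell index i from 1
                return 0 if i == 1 else 2 * i - 3

            def col_B(i):
                return 2 * i - 2

            row = 0
            for i in range(1, L):  # interface between shell i and i+1 at r_i
                r = self._nradii[i - 1]
                rn, rmn = r**n, r ** -(n + 1)
                drn, drmn = n * r ** (n - 1), -(n + 1) * r ** -(n + 2)
                si, so = self.sigmas[i - 1], self.sigmas[i]
                # potential continuity
                A[row, col_A(i)] += rn
                if i > 1:
                    A[row, col_B(i)] += rmn
                A[row, col_A(i + 1)] -= rn
                A[row, col_B(i + 1)] -= rmn
                if i == 1:
                    rhs[row] = -rmn  # source term s_n r^-(n+1), s_n = 1
                row += 1
                # radial current continuity
                A[row, col_A(i)] += si * drn
                if i > 1:
                    A[row, col_B(i)] += si * drmn
                A[row, col_A(i + 1)] -= so * drn
                A[row, col_B(i + 1)] -= so * drmn
                if i == 1:
                    rhs[row] = -si * drmn
                row += 1
            # insulating outer boundary at R
            A[row, col_A(L)] = n * R ** (n - 1)
            A[row, col_B(L)] = -(n + 1) * R ** -(n + 2)
            # row equilibration for conditioning at large n
            scale = np.abs(A).max(axis=1, keepdims=True)
            sol = np.linalg.solve(A / scale, rhs / scale.ravel())
            c[n] = sol[col_A(L)] * R**n + sol[col_B(L)] * R ** -(n + 1)
        return c

    def potential(self, dip_pos: np.ndarray, dip_moment: np.ndarray,
                  electrodes: np.ndarray) -> np.ndarray:
        """Scalp potential at unit-direction electrode positions scaled to
        the scalp radius; ``dip_pos`` in the same units as the radii."""
        R = self.scalp_radius
        p = np.asarray(dip_pos, dtype=float) / R
        q = np.asarray(dip_moment, dtype=float)
        E = np.asarray(electrodes, dtype=float) / R
        b = np.linalg.norm(p)
        if b >= self._nradii[0]:
            raise ValueError("source point outside the brain shell")
        if b < 1e-12:
            p_hat = np.array([0.0, 0.0, 1.0])
            b = 0.0
        else:
            p_hat = p / b
        e_hat = E / np.linalg.norm(E, axis=1, keepdims=True)
        x = np.clip(e_hat @ p_hat, -1.0, 1.0)

        q_r = float(q @ p_hat)
        q_t = q - q_r * p_hat
        e_perp = e_hat - x[:, None] * p_hat[None, :]
        t_dot = e_perp @ q_t

        N = self.n_degrees
        # Legendre P_n(x) and derivatives P_n'(x) by upward recurrence
        Pnm1 = np.ones_like(x)
        Pn = x.copy()
        dPnm1 = np.zeros_like(x)
        dPn = np.ones_like(x)
        # b^(n-1) ladder; at b=0 only n=1 contributes
        V = np.zeros(len(e_hat))
        bpow = 1.0
        for n in range(1, N + 1):
            cn = self._transfer[n]
            V += cn * bpow * (n * q_r * Pn + t_dot * dPn)
            if n < N:
                Pnp1 = ((2 * n + 1) * x * Pn - n * Pnm1) / (n + 1)
                # P_{n+1}'(x) = P_{n-1}'(x) + (2n+1) P_n(x)
                dPnp1 = dPnm1 + (2 * n + 1) * Pn
                Pnm1, Pn = Pn, Pnp1
                dPnm1, dPn = dPn, dPnp1
                bpow *= b
                if bpow == 0.0:
                    break
        # 1/R^2: potentials of a unit dipole scale with inverse length squared
        return V / (4.0 * np.pi * self.sigmas[0] * R**2)


def _cubic_grid(max_radius: float, spacing: float) -> np.ndarray:
    half = np.floor(max_radius / spacing)
    axis = np.arange(-half, half + 1) * spacing
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return pts[np.linalg.norm(pts, axis=1) <= max_radius]


def spherical_head_leadfield(
    montage: Montage,
    grid_spacing: float = 0.2,
    radii=DEFAULT_RADII,
    sigmas=DEFAULT_SIGMAS,
    brain_fill: float = DEFAULT_BRAIN_FILL,
    n_degrees: int = 160,
) -> Leadfield:
    """Three-shell concentric-sphere leadfield on a cubic source grid.

    Electrodes are the montage positions scaled to the scalp radius; the
    source grid is a cubic lattice with the given spacing kept strictly
    inside the brain shell (``|r| <= brain_fill * brain_radius``). Gains for
    the three cartesian unit dipole orientations are average-referenced
    across channels.
    """
    model = ShellModel(radii=radii, sigmas=sigmas, n_degrees=n_degrees)
    electrodes = montage.positions * model.scalp_radius
    grid = _cubic_grid(brain_fill * model.brain_radius, grid_spacing)
    gains = np.empty((len(grid), 3, montage.n_channels))
    eye = np.eye(3)
    for i, pos in enumerate(grid):
        for o in range(3):
            v = model.potential(pos, eye[o], electrodes)
            gains[i, o] = v - v.mean()
    return Leadfield(gains=gains, positions=grid, ch_names=montage.names)


# ---------------------------------------------------------------------------
# interchange
# ---------------------------------------------------------------------------

def save_leadfield(lf: Leadfield, path) -> None:
    """HDF5 container with gains, positions and channel labels."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("gains", data=lf.gains)
        fh.create_dataset("positions", data=lf.positions)
        fh.create_dataset(
            "ch_names", data=np.array(lf.ch_names, dtype=h5py.string_dtype())
        )


def load_leadfield(path) -> Leadfield:
    with h5py.File(path, "r") as fh:
        return Leadfield(
            gains=fh["gains"][()],
            positions=fh["positions"][()],
            ch_names=tuple(s.decode() for s in fh["ch_names"][()]),
        )
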