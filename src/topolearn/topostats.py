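"""Topographic randomization statistics for multi-subject ERP data.

Three tests share one randomization engine:

* **TCT** (topographic consistency test) — per timeframe, is there a scalp
  map shared across subjects? Effect size: GFP of the across-subject mean
  map. Null: electrode values shuffled within each subject's map before
  averaging, destroying shared spatial structure while keeping each
  subject's value distribution.
* **TANCOVA** (topographic analysis of covariance) — per timeframe, does
  the scalp topography covary with a per-subject scalar (d')? Effect size:
  GFP of the covariance map V = M^T u (subjects-by-electrodes potentials M
  and covariate u, both mean-centered across subjects, scaled by 1/(n-1)).
  Null: permute the covariate across subjects. Run on amplitude-normalized
  maps (each subject/timeframe map scaled to GFP 1) to isolate differences
  of topographic shape from differences of field strength.
* **GFP covariation** — per timeframe, does overall field strength covary
  with d'? Effect size: |covariance| (or |correlation|) between per-subject
  GFP and the covariate. Null: permute the covariate.

p-values count ties as extreme, p = (1 + #{null >= observed}) / (1 + n_perm),
which is valid (super-uniform under the null) and never exactly zero.
Significant timeframes are kept only in runs lasting at least 20 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .datasets import CovariateSeries, ErpDataset, check_alignment

__all__ = [
    "CovarianceMap",
    "RandomizationResult",
    "SignificanceWindows",
    "gfp",
    "normalize_gfp",
    "covariance_map",
    "window_covariance_map",
    "tancova",
    "tct",
    "gfp_covariation",
    "significant_windows",
    "spatial_correlation",
    "subdivide_and_merge",
]


# ---------------------------------------------------------------------------
# maps and effect sizes
# ---------------------------------------------------------------------------

def gfp(values: np.ndarray) -> float:
    """Global field power: root mean square across electrodes.

    For zero-mean (average-referenced) maps this equals the population
    standard deviation of the electrode values.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] < 2:
        raise ValueError("GFP needs at least two electrodes")
    g = np.sqrt(np.mean(v**2, axis=-1))
    return float(g) if v.ndim == 1 else g


def normalize_gfp(values: np.ndarray) -> np.ndarray:
    """Scale a map (last axis = electrodes) to unit global field power."""
    v = np.asarray(values, dtype=float)
    g = np.atleast_1d(gfp(v))
    if np.any(g == 0):
        raise ZeroDivisionError("cannot normalize a zero-GFP map")
    return v / g if v.ndim == 1 else v / g[..., None]


@dataclass(frozen=True)
class CovarianceMap:
    """Per-electrode covariance with the covariate at a timeframe/window."""

    values: np.ndarray = field(repr=False)
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def gfp(self) -> float:
        """The map's global field power — the TANCOVA effect size."""
        return gfp(self.values)

    def normalized(self) -> "CovarianceMap":
        return CovarianceMap(normalize_gfp(self.values), self.label)


def covariance_map(
    erps: ErpDataset, u: CovariateSeries, t_ms: float
) -> CovarianceMap:
    """Covariance map V = M^T u at one timeframe.

    M (subjects x electrodes) and u are mean-centered across subjects and
    the product is scaled by 1/(n-1), giving the per-electrode sample
    covariance between potential and covariate.
    """
    check_alignment(erps, u)
    n = erps.n_subjects
    if n < 3:
        raise ValueError("covariance map needs at least 3 subjects")
    ti = erps.time_index(t_ms)
    M = erps.data[:, :, ti]
    Mc = M - M.mean(axis=0, keepdims=True)
    uc = u.values - u.values.mean()
    return CovarianceMap(Mc.T @ uc / (n - 1), label=f"{erps.times_ms[ti]:.1f} ms")


def window_covariance_map(
    erps: ErpDataset, u: CovariateSeries, window_ms: tuple[float, float]
) -> CovarianceMap:
    """Time-averaged covariance map over a half-open [start, end) window."""
    check_alignment(erps, u)
    times = erps.times_ms
    sel = (times >= window_ms[0]) & (times < window_ms[1])
    if not sel.any():
        raise ValueError(f"window {window_ms} contains no timeframes")
    X = erps.data[:, :, sel]
    Xc = X - X.mean(axis=0, keepdims=True)
    uc = u.values - u.values.mean()
    maps = np.einsum("sct,s->ct", Xc, uc) / (erps.n_subjects - 1)
    return CovarianceMap(
        maps.mean(axis=1), label=f"{window_ms[0]:.0f}-{window_ms[1]:.0f} ms"
    )


def spatial_correlation(a: CovarianceMap, b: CovarianceMap) -> float:
    """Pearson correlation of two maps across electrodes."""
    va, vb = a.values, b.values
    if va.shape != vb.shape:
        raise ValueError("maps have different montages")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("spatial correlation undefined for a constant map")
    return float(sp_stats.pearsonr(va, vb).statistic)


# ---------------------------------------------------------------------------
# randomization engine
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    """Per-timeframe observed effects, p-values and bookkeeping."""

    times_ms: np.ndarray
    effect: np.ndarray
    p: np.ndarray
    n_perm: int
    seed: int | None
    sfreq: float
    statistic: str = ""
    maps: np.ndarray | None = field(default=None, repr=False)  # (T, C)
    null: np.ndarray | None = field(default=None, repr=False)  # (P, T)
    excluded: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.asarray(self.p < alpha)


def _permutation_indices(
    rng: np.random.Generator, n_perm: int, n: int
) -> np.ndarray:
    """n_perm independent uniform random permutations of range(n)."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _check_n_perm(n_perm: int, allow_small: bool) -> None:
    if n_perm < 100 and not allow_small:
        raise ValueError(
            "n_perm < 100 is statistically meaningless; pass allow_small=True "
            "to override"
        )


def _p_from_counts(counts: np.ndarray, n_perm: int) -> np.ndarray:
    return (1.0 + counts) / (1.0 + n_perm)


def tancova(
    erps: ErpDataset,
    u: CovariateSeries,
    n_perm: int = 5000,
    alpha: float = 0.05,
    normalize: bool = True,
    seed=None,
    frames: np.ndarray | None = None,
    keep_null: bool = False,
    allow_small: bool = False,
    perm_block: int = 500,
) -> RandomizationResult:
    """Topographic analysis of covariance with a permutation null.

    Parameters
    ----------
    frames : boolean array (n_times,), optional
        Restriction to a consistency-validated period (e.g. TCT-significant
        frames). Frames outside get p = NaN. When omitted the full epoch is
        analyzed.
    normalize : bool
        Scale every subject/timeframe map to GFP 1 before computing
        covariance maps (the default), so the test sees topographic shape
        only. Frames where any subject has a zero-GFP map are excluded.
    keep_null : bool
        Store the (n_perm, n_times) null effect sizes (memory permitting).
    """
    check_alignment(erps, u)
    _check_n_perm(n_perm, allow_small)
    n, _, n_times = erps.data.shape
    if n < 3:
        raise ValueError("TANCOVA needs at least 3 subjects")
    rng = np.random.default_rng(seed)

    X = erps.data
    excluded = np.zeros(n_times, dtype=bool)
    if normalize:
        g = np.sqrt(np.mean(X**2, axis=1))  # (S, T)
        excluded |= (g == 0).any(axis=0)
        g = np.where(g == 0, 1.0, g)
        X = X / g[:, None, :]
    if frames is not None:
        excluded |= ~np.asarray(frames, dtype=bool)

    Xc = X - X.mean(axis=0, keepdims=True)
    uc = u.values - u.values.mean()

    maps = np.einsum("sct,s->ct", Xc, uc) / (n - 1)  # (C, T)
    effect = np.sqrt(np.mean(maps**2, axis=0))  # GFP per frame

    flat = Xc.reshape(n, -1)  # (S, C*T)
    counts = np.zeros(n_times)
    null_store = [] if keep_null else None
    for start in range(0, n_perm, perm_block):
        idx = _permutation_indices(rng, min(perm_block, n_perm - start), n)
        U = uc[idx]  # (B, S)
        Vn = (U @ flat).reshape(len(idx), erps.n_channels, n_times) / (n - 1)
        null_eff = np.sqrt(np.mean(Vn**2, axis=1))  # (B, T)
        counts += (null_eff >= effect[None, :]).sum(axis=0)
        if keep_null:
            null_store.append(null_eff)

    p = _p_from_counts(counts, n_perm)
    p[excluded] = np.nan
    return RandomizationResult(
        times_ms=erps.times_ms,
        effect=effect,
        p=p,
        n_perm=n_perm,
        seed=seed,
        sfreq=erps.sfreq,
        statistic="gfp(covariance map)" + (" [GFP=1 maps]" if normalize else ""),
        maps=maps.T,
        null=np.concatenate(null_store) if keep_null else None,
        excluded=excluded,
    )


def tct(
    erps: ErpDataset,
    n_perm: int = 5000,
    seed=None,
    allow_small: bool = False,
) -> RandomizationResult:
    """Topographic consistency test across subjects.

    Observed effect per timeframe: GFP of the grand-mean map. Null:
    electrode values shuffled within each subject before averaging (one
    shuffle per subject per permutation, reused across timeframes; each
    frame's p-value is exact on its own).
    """
    _check_n_perm(n_perm, allow_small)
    n, n_ch, n_times = erps.data.shape
    rng = np.random.default_rng(seed)
    X = erps.data
    effect = np.sqrt(np.mean(X.mean(axis=0) ** 2, axis=0))

    if n == 1:
        # degenerate: the mean map is the single subject's map
        return RandomizationResult(
            times_ms=erps.times_ms,
            effect=effect,
            p=np.full(n_times, np.nan),
            n_perm=0,
            seed=seed,
            sfreq=erps.sfreq,
            statistic="gfp(mean map) [degenerate: single subject]",
        )

    counts = np.zeros(n_times)
    subj = np.arange(n)[:, None]
    for _ in range(n_perm):
        idx = _permutation_indices(rng, n, n_ch)  # (S, C)
        shuffled = X[subj, idx, :]  # (S, C, T)
        null_eff = np.sqrt(np.mean(shuffled.mean(axis=0) ** 2, axis=0))
        counts += null_eff >= effect
    return RandomizationResult(
        times_ms=erps.times_ms,
        effect=effect,
        p=_p_from_counts(counts, n_perm),
        n_perm=n_perm,
        seed=seed,
        sfreq=erps.sfreq,
        statistic="gfp(mean map)",
    )


def gfp_covariation(
    erps: ErpDataset,
    u: CovariateSeries,
    n_perm: int = 5000,
    seed=None,
    effect_size: str = "covariance",
    frames: np.ndarray | None = None,
    allow_small: bool = False,
) -> RandomizationResult:
    """Covariation between per-subject global field power and the covariate.

    ``effect_size`` is ``"covariance"`` (default) or ``"correlation"``; the
    observed statistic is its absolute value, with a permutation null over
    the covariate.
    """
    check_alignment(erps, u)
    _check_n_perm(n_perm, allow_small)
    if effect_size not in ("covariance", "correlation"):
        raise ValueError("effect_size must be 'covariance' or 'correlation'")
    n, _, n_times = erps.data.shape
    if n < 3:
        raise ValueError("GFP covariation needs at least 3 subjects")
    rng = np.random.default_rng(seed)

    g = np.sqrt(np.mean(erps.data**2, axis=1))  # (S, T)
    gc = g - g.mean(axis=0, keepdims=True)
    uc = u.values - u.values.mean()
    if effect_size == "correlation":
        denom = gc.std(axis=0, ddof=1) * uc.std(ddof=1)
        denom = np.where(denom == 0, np.inf, denom) * (n - 1)
    else:
        denom = float(n - 1)
    effect = np.abs(gc.T @ uc) / denom

    idx = _permutation_indices(rng, n_perm, n)
    null = np.abs(uc[idx] @ gc) / denom  # (P, T)
    counts = (null >= effect[None, :]).sum(axis=0)
    p = _p_from_counts(counts, n_perm)
    if frames is not None:
        p[~np.asarray(frames, dtype=bool)] = np.nan
    return RandomizationResult(
        times_ms=erps.times_ms,
        effect=effect,
        p=p,
        n_perm=n_perm,
        seed=seed,
        sfreq=erps.sfreq,
        statistic=f"|{effect_size}(GFP, u)|",
    )


# ---------------------------------------------------------------------------
# significance windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignificanceWindows:
    """Disjoint, sorted, half-open [start_ms, end_ms) significant intervals."""

    windows: tuple[tuple[float, float], ...]
    min_duration_ms: float
    alpha: float

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)


def significant_windows(
    result: RandomizationResult,
    alpha: float = 0.05,
    min_duration_ms: float = 20.0,
) -> SignificanceWindows:
    """Maximal runs of consecutive p < alpha frames lasting at least
    ``min_duration_ms`` (frame count ``ceil(min_duration_ms * sfreq / 1000)``).
    """
    sig = result.significant(alpha)
    min_frames = int(np.ceil(min_duration_ms * result.sfreq / 1000.0))
    dt = 1000.0 / result.sfreq
    times = result.times_ms
    windows = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_frames:
                windows.append((float(times[i]), float(times[j] + dt)))
            i = j + 1
        else:
            i += 1
    return SignificanceWindows(tuple(windows), min_duration_ms, alpha)


# ---------------------------------------------------------------------------
# sub-window extraction and merging
# ---------------------------------------------------------------------------

def _clip_subwindow(center: float, width: float, bounds) -> tuple[float, float]:
    lo, hi = bounds
    start = max(lo, min(center - width / 2.0, hi - width))
    return (start, min(start + width, hi))


def subdivide_and_merge(
    result: RandomizationResult,
    erps: ErpDataset,
    u: CovariateSeries,
    window_ms: tuple[float, float],
    subwindow_ms: float = 70.0,
    merge_r: float = 0.9,
) -> list[tuple[tuple[float, float], CovarianceMap]]:
    """Split a long significant window into ~``subwindow_ms`` sub-windows
    centred on local maxima of the effect-size time course, then merge
    adjacent sub-windows whose time-averaged covariance maps are spatially
    similar (Pearson r >= ``merge_r``).

    A window shorter than ``subwindow_ms`` is returned whole. Merged
    windows span from the first member's start to the last member's end and
    their map is recomputed over that span.
    """
    lo, hi = window_ms
    if hi - lo <= subwindow_ms:
        return [(window_ms, window_covariance_map(erps, u, window_ms))]

    times = result.times_ms
    sel = np.flatnonzero((times >= lo) & (times < hi))
    curve = result.effect[sel]

    peaks, _ = sp_signal.find_peaks(curve)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(curve))])
    # greedy selection of peaks by effect size, at least one sub-window apart
    order = peaks[np.argsort(curve[peaks])[::-1]]
    centers: list[float] = []
    for pk in order:
        t_pk = float(times[sel[pk]])
        if all(abs(t_pk - c) >= subwindow_ms for c in centers):
            centers.append(t_pk)
    centers.sort()

    subwins = [_clip_subwindow(c, subwindow_ms, (lo, hi)) for c in centers]
    items = [(w, window_covariance_map(erps, u, w)) for w in subwins]

    # merge chains of adjacent similar maps
    merged = True
    while merged and len(items) > 1:
        merged = False
        for i in range(len(items) - 1):
            (wa, ma), (wb, mb) = items[i], items[i + 1]
            if spatial_correlation(ma, mb) >= merge_r:
                span = (wa[0], wb[1])
                items[i : i + 2] = [
                    (span, window_covariance_map(erps, u, span))
                ]
                merged = True
                break
    return items
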