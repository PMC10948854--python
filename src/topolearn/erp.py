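"""Per-subject ERP assembly: artifact rejection, channel interpolation,
averaging and average re-referencing.

Rejection follows two automatic rules applied per epoch and channel:

* amplitude — any sample beyond +/-80 uV,
* peak-to-peak — max minus min exceeding 200 uV within any 200 ms
  sliding window (window advanced sample by sample).

Bad channels flagged externally (recurrent artifacts) are rebuilt from
neighbouring electrodes by inverse great-circle-distance weighting of the
k nearest good channels. Accepted epochs are averaged and the average is
re-referenced to the common average; no baseline correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .montage import Montage


@dataclass
class EpochSet:
    """Single-subject epochs: ``epochs x channels x times`` in microvolts."""

    data: np.ndarray = field(repr=False)
    sfreq: float
    window_ms: tuple[float, float] = (-100.0, 1000.0)
    ch_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, times)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.ch_names and len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names do not match channel axis")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


class NoAcceptedEpochsError(RuntimeError):
    """All epochs rejected: the subject is unusable."""


def reject_epochs(
    epochs: EpochSet,
    amp_limit_uv: float = 80.0,
    p2p_limit_uv: float = 200.0,
    p2p_window_ms: float = 200.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs breaching the amplitude or sliding peak-to-peak rule.

    Returns the surviving epochs and a per-epoch report with boolean
    columns ``amplitude`` and ``p2p`` and the combined ``rejected`` flag.
    An empty result (subject unusable) is legal here and surfaces as an
    error only when averaging is attempted.
    """
    n_times = epochs.data.shape[2]
    win = int(np.floor(p2p_window_ms / 1000.0 * epochs.sfreq))
    if win > n_times:
        raise ValueError("p2p window longer than the epoch")
    win = max(win, 1)

    amp_bad = (np.abs(epochs.data) > amp_limit_uv).any(axis=(1, 2))
    # sliding max-min along time, window advanced sample by sample
    mx = maximum_filter1d(epochs.data, size=win, axis=2, mode="nearest")
    mn = minimum_filter1d(epochs.data, size=win, axis=2, mode="nearest")
    # restrict to fully contained windows (filters pad at the edges)
    half_lo = (win - 1) // 2
    half_hi = win - 1 - half_lo
    sl = slice(half_lo, n_times - half_hi)
    p2p_bad = ((mx - mn)[:, :, sl] > p2p_limit_uv).any(axis=(1, 2))

    rejected = amp_bad | p2p_bad
    report = pd.DataFrame(
        {
            "epoch": np.arange(epochs.n_epochs),
            "amplitude": amp_bad,
            "p2p": p2p_bad,
            "rejected": rejected,
        }
    )
    return replace(epochs, data=epochs.data[~rejected]), report


def interpolation_weights(
    montage: Montage, bad_channels: list[str], k_neighbors: int = 4
) -> np.ndarray:
    """Rows of normalized inverse-distance weights over good channels, one
    per bad channel (channels ordered as in the montage)."""
    bad_idx = [montage.index(b) for b in bad_channels]
    good_idx = [i for i in range(montage.n_channels) if i not in set(bad_idx)]
    if not good_idx:
        raise ValueError("cannot interpolate: all channels are bad")
    dist = montage.great_circle_distances()
    weights = np.zeros((len(bad_idx), montage.n_channels))
    for row, bi in enumerate(bad_idx):
        d = dist[bi, good_idx]
        order = np.argsort(d)[: min(k_neighbors, len(good_idx))]
        w = 1.0 / np.maximum(d[order], 1e-9)
        w /= w.sum()
        for o, wi in zip(order, w):
            weights[row, good_idx[o]] = wi
    return weights


def interpolate_channels(
    epochs: EpochSet,
    bad_channels: list[str],
    montage: Montage,
    k_neighbors: int = 4,
) -> EpochSet:
    """Replace bad channels by distance-weighted combinations of their
    nearest good neighbours; good channels are untouched."""
    if not bad_channels:
        return epochs
    unknown = set(bad_channels) - set(montage.names)
    if unknown:
        raise ValueError(f"bad channels not in montage: {sorted(unknown)}")
    if len(set(bad_channels)) >= montage.n_channels:
        raise ValueError("cannot interpolate: all channels are bad")
    weights = interpolation_weights(montage, bad_channels, k_neighbors)
    data = epochs.data.copy()
    for row, name in enumerate(bad_channels):
        bi = montage.index(name)
        data[:, bi, :] = np.einsum("c,ect->et", weights[row], epochs.data)
    return replace(epochs, data=data)


def average_and_rereference(epochs: EpochSet) -> np.ndarray:
    """Mean over epochs, then common-average reference per timeframe.

    No baseline correction is applied. Returns ``channels x times``.
    """
    if epochs.n_epochs == 0:
        raise NoAcceptedEpochsError("no epochs to average")
    erp = epochs.data.mean(axis=0)
    return erp - erp.mean(axis=0, keepdims=True)


def assemble_subject_erp(
    epochs: EpochSet,
    montage: Montage,
    bad_channels: list[str] | None = None,
    bad_epochs: list[int] | None = None,
    amp_limit_uv: float = 80.0,
    p2p_limit_uv: float = 200.0,
    p2p_window_ms: float = 200.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Full per-subject chain: drop externally flagged epochs (the manual-
    inspection hook), apply automatic rejection, interpolate flagged
    channels, average and re-reference."""
    data = epochs.data
    if bad_epochs:
        keep = np.setdiff1d(np.arange(data.shape[0]), np.asarray(bad_epochs))
        data = data[keep]
    eps = replace(epochs, data=data)
    eps, report = reject_epochs(eps, amp_limit_uv, p2p_limit_uv, p2p_window_ms)
    if bad_channels:
        eps = interpolate_channels(eps, bad_channels, montage)
    return average_and_rereference(eps), report


def load_epochs_dir(directory, sfreq: float, window_ms=(-100.0, 1000.0)) -> EpochSet:
    """Read one delimited file per epoch (rows = timeframes, cols = channels)."""
    files = sorted(Path(directory).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no epoch files under {directory}")
    data = np.stack([np.loadtxt(f, delimiter="\t").T for f in files])
    return EpochSet(data=data, sfreq=sfreq, window_ms=tuple(window_ms))
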