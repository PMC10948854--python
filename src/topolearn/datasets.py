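"""Core data containers: multi-subject ERP stacks and per-subject covariates.

An :class:`ErpDataset` holds one average ERP per subject as a dense
``subjects x channels x timeframes`` array in microvolts, together with the
sampling rate, the epoch window relative to stimulus onset, the montage and
the subject order. The per-subject behavioural covariate (d') travels in a
:class:`CovariateSeries` whose subject order must match the ERP stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, load_montage, save_montage

AVERAGE_REFERENCE_ATOL = 1e-8


@dataclass
class ErpDataset:
    """Stacked per-subject average ERPs.

    Attributes
    ----------
    data : ndarray, shape (n_subjects, n_channels, n_times)
        Average-referenced scalp potentials, microvolts.
    sfreq : float
        Sampling rate in Hz.
    window_ms : (float, float)
        Epoch limits relative to stimulus onset, in ms; the first sample
        sits at ``window_ms[0]``.
    montage : Montage
    subject_ids : tuple of str
    """

    data: np.ndarray = field(repr=False)
    sfreq: float
    window_ms: tuple[float, float]
    montage: Montage
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (subjects, channels, times)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids do not match subject axis")
        if not np.isfinite(self.data).all():
            raise ValueError("ERP data contain non-finite values")
        self.subject_ids = tuple(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.window_ms[0] + np.arange(self.n_times) * 1000.0 / self.sfreq

    def is_average_referenced(self, atol: float = 1e-6) -> bool:
        return bool(np.abs(self.data.mean(axis=1)).max() <= atol)

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))


@dataclass
class CovariateSeries:
    """Per-subject scalar covariate (d' in the learning study)."""

    subject_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.subject_ids) != self.values.size:
            raise ValueError("subject_ids and values differ in length")
        if not np.isfinite(self.values).all():
            raise ValueError("covariate values must be finite")
        self.subject_ids = tuple(self.subject_ids)

    def __len__(self) -> int:
        return self.values.size

    def aligned_to(self, subject_ids) -> "CovariateSeries":
        """Reorder to a given subject order; error on any missing subject."""
        lookup = dict(zip(self.subject_ids, self.values))
        try:
            vals = [lookup[s] for s in subject_ids]
        except KeyError as err:
            raise KeyError(f"covariate missing for subject {err}") from None
        return CovariateSeries(tuple(subject_ids), np.array(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "dprime": self.values})


def check_alignment(erps: ErpDataset, covariate: CovariateSeries) -> None:
    if erps.subject_ids != covariate.subject_ids:
        raise ValueError(
            "ERP dataset and covariate series have different subject orders; "
            "use CovariateSeries.aligned_to(erps.subject_ids)"
        )


# ---------------------------------------------------------------------------
# delimited-text interchange
# ---------------------------------------------------------------------------

def save_erp_dataset(erps: ErpDataset, directory) -> None:
    """Write one delimited matrix per subject (rows = timeframes, columns =
    electrodes) plus a JSON sidecar and a montage file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, mat in zip(erps.subject_ids, erps.data):
        np.savetxt(directory / f"{sid}.tsv", mat.T, fmt="%.6f", delimiter="\t")
    sidecar = {
        "sfreq": erps.sfreq,
        "window_ms": list(erps.window_ms),
        "subject_ids": list(erps.subject_ids),
        "channel_names": list(erps.montage.names),
        "units": "microvolt",
    }
    (directory / "dataset.json").write_text(json.dumps(sidecar, indent=2))
    save_montage(erps.montage, directory / "montage.txt")


def load_erp_dataset(directory) -> ErpDataset:
    directory = Path(directory)
    sidecar = json.loads((directory / "dataset.json").read_text())
    montage = load_montage(directory / "montage.txt")
    if tuple(montage.names) != tuple(sidecar["channel_names"]):
        raise ValueError("montage file and sidecar disagree on channels")
    data = np.stack(
        [
            np.loadtxt(directory / f"{sid}.tsv", delimiter="\t").T
            for sid in sidecar["subject_ids"]
        ]
    )
    return ErpDataset(
        data=data,
        sfreq=float(sidecar["sfreq"]),
        window_ms=tuple(sidecar["window_ms"]),
        montage=montage,
        subject_ids=tuple(sidecar["subject_ids"]),
    )


def save_covariates(covariate: CovariateSeries, path) -> None:
    covariate.to_frame().to_csv(path, index=False)


def load_covariates(path) -> CovariateSeries:
    df = pd.read_csv(path)
    return CovariateSeries(tuple(df["subject_id"].astype(str)), df["dprime"].to_numpy())
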