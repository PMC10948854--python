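"""Signal-detection scoring of associative-learning trial logs.

Each trial presents either a learned color-shape association (target) or a
recombined one (lure); the subject endorses ("yes") or rejects ("no") it, or
times out. Trials are tabulated into the SDT contingency table and sensitivity
is the probit difference

    d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate)

with the hit rate taken over answered target trials and the false-alarm rate
over answered lure trials. Timeout trials never enter the table.

A trial log is a :class:`pandas.DataFrame` with columns ``trial`` (strictly
increasing 1-based index), ``stimulus`` ("target" / "lure"), ``response``
("yes" / "no" / "timeout") and ``rt_ms`` (NaN for timeouts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

TRIAL_COLUMNS = ("trial", "stimulus", "response", "rt_ms")

#: Hard cap on the number of trials a session may contain.
MAX_TRIALS = 504


class UndefinedSensitivityError(ValueError):
    """Raised when d' is requested without answered targets and lures."""


@dataclass(frozen=True)
class ConfusionCounts:
    """SDT contingency cells over answered trials."""

    hit: int
    miss: int
    fa: int
    cr: int

    def __post_init__(self) -> None:
        if min(self.hit, self.miss, self.fa, self.cr) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_targets(self) -> int:
        return self.hit + self.miss

    @property
    def n_lures(self) -> int:
        return self.fa + self.cr

    @property
    def total(self) -> int:
        return self.n_targets + self.n_lures


def validate_trial_log(log: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRIAL_COLUMNS) - set(log.columns)
    if missing:
        raise ValueError(f"trial log missing columns {sorted(missing)}")
    trials = log["trial"].to_numpy()
    if len(trials) and not (np.diff(trials) > 0).all():
        raise ValueError("trial indices must be strictly increasing")
    answered = log["response"] != "timeout"
    rts = log.loc[answered, "rt_ms"]
    if (rts <= 0).any():
        raise ValueError("rt_ms must be positive for answered trials")
    return log


def tabulate(log: pd.DataFrame) -> ConfusionCounts:
    """Tabulate a trial log into the SDT contingency table.

    Timeout trials are excluded; answered trials partition into
    hit / miss / false alarm / correct rejection.
    """
    validate_trial_log(log)
    answered = log[log["response"] != "timeout"]
    is_target = answered["stimulus"] == "target"
    said_yes = answered["response"] == "yes"
    return ConfusionCounts(
        hit=int((is_target & said_yes).sum()),
        miss=int((is_target & ~said_yes).sum()),
        fa=int((~is_target & said_yes).sum()),
        cr=int((~is_target & ~said_yes).sum()),
    )


def _rates(counts: ConfusionCounts, correction: str) -> tuple[float, float]:
    if counts.n_targets == 0 or counts.n_lures == 0:
        raise UndefinedSensitivityError(
            "d' undefined: need at least one answered target and one answered lure"
        )
    hr = counts.hit / counts.n_targets
    far = counts.fa / counts.n_lures
    if correction == "half-count":
        # 0 -> 1/(2N), 1 -> 1 - 1/(2N) on the respective trial count
        if hr == 0.0:
            hr = 0.5 / counts.n_targets
        elif hr == 1.0:
            hr = 1.0 - 0.5 / counts.n_targets
        if far == 0.0:
            far = 0.5 / counts.n_lures
        elif far == 1.0:
            far = 1.0 - 0.5 / counts.n_lures
    elif correction == "error":
        if hr in (0.0, 1.0) or far in (0.0, 1.0):
            raise UndefinedSensitivityError(
                "extreme hit or false-alarm rate with correction='error'"
            )
    elif correction != "none":
        raise ValueError(f"unknown correction policy {correction!r}")
    return hr, far


def dprime(counts: ConfusionCounts, correction: str = "half-count") -> float:
    """Equal-variance SDT sensitivity, Phi^-1(HR) - Phi^-1(FAR).

    Parameters
    ----------
    counts : ConfusionCounts
    correction : {"half-count", "none", "error"}
        Policy for hit / false-alarm rates of exactly 0 or 1, whose probit
        is infinite. ``"half-count"`` (default) replaces rate 0 by 1/(2N)
        and rate 1 by 1 - 1/(2N); ``"none"`` lets infinities through;
        ``"error"`` raises.
    """
    hr, far = _rates(counts, correction)
    return float(norm.ppf(hr) - norm.ppf(far))


def dprime_from_log(log: pd.DataFrame, correction: str = "half-count") -> float:
    return dprime(tabulate(log), correction=correction)


def is_correct(log: pd.DataFrame) -> np.ndarray:
    """Per-trial correctness: yes-to-target or no-to-lure; timeouts count
    as incorrect (the task's feedback labels slow responses as failures)."""
    is_target = (log["stimulus"] == "target").to_numpy()
    resp = log["response"].to_numpy()
    return (is_target & (resp == "yes")) | (~is_target & (resp == "no"))


def learning_criterion_reached(
    log: pd.DataFrame,
    window: int = 48,
    threshold: float = 0.95,
    max_trials: int = MAX_TRIALS,
):
    """Earliest trial at which the trailing-window accuracy strictly exceeds
    ``threshold``.

    Scans windows of ``window`` consecutive trials ending at trials
    ``window .. min(len(log), max_trials)`` and returns the 1-based index of
    the last trial of the first window whose proportion correct is strictly
    greater than ``threshold``, or ``None`` if the criterion is never met.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    validate_trial_log(log)
    if window > len(log):
        raise ValueError("window longer than the trial log")
    correct = is_correct(log).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(correct)])
    n_end = min(len(log), max_trials)
    for end in range(window, n_end + 1):
        if (csum[end] - csum[end - window]) / window > threshold:
            return int(log["trial"].iloc[end - 1])
    return None


def score_log(log: pd.DataFrame, correction: str = "half-count") -> dict:
    """Full behavioural summary of one subject's log."""
    counts = tabulate(log)
    return {
        "hit": counts.hit,
        "miss": counts.miss,
        "fa": counts.fa,
        "cr": counts.cr,
        "n_timeouts": int((log["response"] == "timeout").sum()),
        "dprime": dprime(counts, correction=correction),
        "reached_at_trial": learning_criterion_reached(log)
        if len(log) >= 48
        else None,
    }
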