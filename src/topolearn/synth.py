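"""Synthetic cohorts: SDT observers and multi-subject ERP datasets with
known covariate-linked topographic structure.

The generator emulates the structure of the learning study it is designed
to exercise: 38 subjects, 64 scalp channels, 512 Hz sampling, epochs from
-100 to +1000 ms, spatially smooth background noise, a shared evoked
response across subjects, and one or more scalp components whose amplitude
is a linear function of the subject's behavioural sensitivity d'. Because
the injected templates, latencies and gains are known, every downstream
statistic can be validated against generative ground truth.

Subject ERP model (channel c, time t, subject s):

    x_s(c, t) = sum_k env_k(t) * (a_k + g_k * d'_s) * T_k(c) + noise_s(c, t)

with each template T_k zero-mean across channels and unit global field
power, ``env_k`` a unit-peak window over the component's latency range
(flat with raised-cosine ramps by default), and spatially (and optionally
temporally) smoothed Gaussian noise. The result is average-referenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .behavior import MAX_TRIALS
from .datasets import CovariateSeries, ErpDataset
from .montage import Montage

# Cohort d' distribution used by default for synthetic covariates:
# mean 1.19, SD 0.51, truncated to the observed range [-0.09, 2.32].
DPRIME_MEAN = 1.19
DPRIME_SD = 0.51
DPRIME_RANGE = (-0.09, 2.32)


# ---------------------------------------------------------------------------
# behavioural observers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverSpec:
    """An equal-variance SDT observer.

    Target evidence ~ Normal(true_dprime, 1), lure evidence ~ Normal(0, 1);
    the observer answers "yes" iff evidence exceeds ``criterion``. A
    ``timeout_rate`` fraction of trials, drawn independently of evidence,
    is marked as timed out.
    """

    true_dprime: float
    criterion: float
    n_targets: int
    n_lures: int
    timeout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_targets < 0 or self.n_lures < 0:
            raise ValueError("trial counts must be non-negative")
        if not 0.0 <= self.timeout_rate <= 1.0:
            raise ValueError("timeout_rate must lie in [0, 1]")


def simulate_trials(obs: ObserverSpec, seed=None) -> pd.DataFrame:
    """Draw one session's trial log from an SDT observer.

    Targets and lures are interleaved in random order. Response times for
    answered trials are drawn from a truncated normal centred near the
    cohort's mean RT (1235 ms); they carry no signal.
    """
    rng = np.random.default_rng(seed)
    n = obs.n_targets + obs.n_lures
    stimulus = np.array(["target"] * obs.n_targets + ["lure"] * obs.n_lures)
    rng.shuffle(stimulus)
    mean = np.where(stimulus == "target", obs.true_dprime, 0.0)
    evidence = rng.standard_normal(n) + mean
    response = np.where(evidence > obs.criterion, "yes", "no").astype(object)
    timeout = rng.random(n) < obs.timeout_rate
    response[timeout] = "timeout"
    rt = np.maximum(rng.normal(1235.0, 180.0, size=n), 200.0)
    rt[timeout] = np.nan
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "stimulus": stimulus,
            "response": response,
            "rt_ms": rt,
        }
    )


def sample_dprime_covariate(
    n_subjects: int,
    seed=None,
    mean: float = DPRIME_MEAN,
    sd: float = DPRIME_SD,
    bounds: tuple[float, float] = DPRIME_RANGE,
    subject_ids=None,
) -> CovariateSeries:
    """Draw per-subject d' values from a truncated normal cohort model."""
    rng = np.random.default_rng(seed)
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    vals = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_subjects, random_state=rng)
    if subject_ids is None:
        subject_ids = tuple(f"S{i + 1:02d}" for i in range(n_subjects))
    return CovariateSeries(tuple(subject_ids), vals)


def simulate_cohort_trials(
    covariate: CovariateSeries,
    n_targets: int = MAX_TRIALS // 2,
    n_lures: int = MAX_TRIALS // 2,
    criterion_fraction: float = 0.5,
    timeout_rate: float = 0.01,
    seed=None,
) -> dict[str, pd.DataFrame]:
    """One trial log per subject, with each observer's generative d' set to
    the subject's covariate value and an unbiased-by-default criterion at
    ``criterion_fraction * d'``."""
    rng = np.random.default_rng(seed)
    logs = {}
    for sid, theta in zip(covariate.subject_ids, covariate.values):
        obs = ObserverSpec(
            true_dprime=float(theta),
            criterion=criterion_fraction * float(theta),
            n_targets=n_targets,
            n_lures=n_lures,
            timeout_rate=timeout_rate,
        )
        logs[sid] = simulate_trials(obs, seed=rng.integers(2**31))
    return logs


# ---------------------------------------------------------------------------
# scalp components and noise
# ---------------------------------------------------------------------------

def topographic_template(
    montage: Montage, center: str, fwhm_deg: float = 60.0
) -> np.ndarray:
    """A smooth scalp blob centred on an electrode, zero-mean and unit-GFP.

    The raw pattern is a Gaussian in great-circle angle from the centre
    electrode with the given full width at half maximum (degrees); it is
    then mean-centred across electrodes and scaled to global field power 1.
    """
    pos = montage.positions
    c = pos[montage.index(center)]
    ang = np.arccos(np.clip(pos @ c, -1.0, 1.0))
    sigma = np.deg2rad(fwhm_deg) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    raw = np.exp(-0.5 * (ang / sigma) ** 2)
    return normalize_template(raw)


def normalize_template(pattern: np.ndarray) -> np.ndarray:
    """Mean-centre across electrodes and scale to unit GFP."""
    t = np.asarray(pattern, dtype=float)
    t = t - t.mean()
    g = np.sqrt(np.mean(t**2))
    if g == 0:
        raise ValueError("template is constant; zero GFP after centering")
    return t / g


@dataclass(frozen=True)
class ComponentSpec:
    """A scalp component with a latency window and covariate coupling.

    ``template`` must be zero-mean across electrodes with unit GFP (use
    :func:`normalize_template`). Subject s contributes
    ``env(t) * (base_amplitude + covariate_gain * d'_s) * template``.
    """

    onset_ms: float
    offset_ms: float
    template: np.ndarray = field(repr=False)
    base_amplitude: float = 1.0  # microvolts at envelope peak
    covariate_gain: float = 0.0  # microvolts per unit d'
    temporal_envelope: str = "tukey"

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("onset_ms must precede offset_ms")
        t = np.asarray(self.template, dtype=float)
        if abs(t.mean()) > 1e-8 or abs(np.sqrt(np.mean(t**2)) - 1.0) > 1e-6:
            raise ValueError(
                "template must be zero-mean with unit GFP; see normalize_template"
            )
        object.__setattr__(self, "template", t)

    def envelope(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-peak temporal window, exactly zero outside [onset_ms, offset_ms).

        ``"tukey"`` (default) holds full amplitude over the central part of
        the window with raised-cosine ramps over the outer quarter at each
        edge, so the component is expressed throughout its stated latency
        range; ``"hann"`` is a raised cosine peaking mid-window; ``"boxcar"``
        is flat.
        """
        phase = (times_ms - self.onset_ms) / (self.offset_ms - self.onset_ms)
        inside = (phase >= 0.0) & (phase < 1.0)
        if self.temporal_envelope == "hann":
            env = np.where(inside, 0.5 * (1.0 - np.cos(2.0 * np.pi * phase)), 0.0)
        elif self.temporal_envelope == "tukey":
            a = 0.25  # ramp fraction of the window at each edge
            ramp_in = 0.5 * (1.0 - np.cos(np.pi * np.clip(phase / a, 0.0, 1.0)))
            ramp_out = 0.5 * (
                1.0 - np.cos(np.pi * np.clip((1.0 - phase) / a, 0.0, 1.0))
            )
            env = np.where(inside, np.minimum(ramp_in, ramp_out), 0.0)
        elif self.temporal_envelope == "boxcar":
            env = inside.astype(float)
        else:
            raise ValueError(f"unknown envelope {self.temporal_envelope!r}")
        return env


@dataclass(frozen=True)
class NoiseSpec:
    """Spatially smooth background noise.

    White Gaussian noise per channel/timeframe is smoothed across the scalp
    with a Gaussian kernel in great-circle angle (``spatial_fwhm_deg``) and
    along time (``temporal_fwhm_ms``, emulating band-limited EEG background),
    then rescaled so every channel keeps standard deviation ``sd_uv``.
    """

    sd_uv: float = 1.0
    spatial_fwhm_deg: float = 30.0
    temporal_fwhm_ms: float = 12.0

    def __post_init__(self) -> None:
        if self.sd_uv < 0:
            raise ValueError("sd_uv must be non-negative")


def _spatial_smoother(montage: Montage, fwhm_deg: float) -> np.ndarray:
    """Row-normalized Gaussian smoothing kernel over electrode distances,
    rescaled so that smoothing preserves per-channel variance of white noise."""
    if fwhm_deg <= 0:
        return np.eye(montage.n_channels)
    ang = montage.great_circle_distances()
    sigma = np.deg2rad(fwhm_deg) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = np.exp(-0.5 * (ang / sigma) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    # unit output variance per channel for unit-variance white input
    w /= np.sqrt((w**2).sum(axis=1, keepdims=True))
    return w


def _draw_noise(
    rng: np.random.Generator,
    noise: NoiseSpec,
    smoother: np.ndarray,
    n_times: int,
    sfreq: float,
) -> np.ndarray:
    n_ch = smoother.shape[0]
    x = rng.standard_normal((n_ch, n_times))
    x = smoother @ x
    if noise.temporal_fwhm_ms > 0:
        sigma_samp = noise.temporal_fwhm_ms / 1000.0 * sfreq
        sigma_samp /= 2.0 * np.sqrt(2.0 * np.log(2.0))
        if sigma_samp > 1e-3:
            x = gaussian_filter1d(x, sigma_samp, axis=1, mode="reflect")
            # empirical re-standardization so sd_uv is honoured exactly
            x /= x.std(axis=1, keepdims=True).clip(min=1e-12)
    return noise.sd_uv * x


# ---------------------------------------------------------------------------
# dataset synthesis
# ---------------------------------------------------------------------------

def simulate_erp_dataset(
    n_subjects: int,
    montage: Montage,
    components: list[ComponentSpec],
    noise: NoiseSpec,
    covariate: CovariateSeries,
    sfreq: float = 512.0,
    epoch_window_ms: tuple[float, float] = (-100.0, 1000.0),
    seed=None,
) -> ErpDataset:
    """Generate one average ERP per subject under the linear component model.

    The output is average-referenced. Generation is reproducible from
    ``seed``; the same seed yields a bit-identical dataset.
    """
    if len(covariate) != n_subjects:
        raise ValueError("covariate length must equal n_subjects")
    for comp in components:
        if comp.onset_ms < epoch_window_ms[0] or comp.offset_ms > epoch_window_ms[1]:
            raise ValueError(
                f"component window [{comp.onset_ms}, {comp.offset_ms}] ms exceeds "
                f"epoch window {epoch_window_ms}"
            )
        if len(comp.template) != montage.n_channels:
            raise ValueError("component template does not match montage size")

    rng = np.random.default_rng(seed)
    n_times = int(round((epoch_window_ms[1] - epoch_window_ms[0]) / 1000.0 * sfreq))
    times = epoch_window_ms[0] + np.arange(n_times) * 1000.0 / sfreq

    envs = [c.envelope(times) for c in components]
    smoother = _spatial_smoother(montage, noise.spatial_fwhm_deg)

    data = np.zeros((n_subjects, montage.n_channels, n_times))
    for s, dp in enumerate(covariate.values):
        for comp, env in zip(components, envs):
            amp = comp.base_amplitude + comp.covariate_gain * dp
            data[s] += amp * np.outer(comp.template, env)
        if noise.sd_uv > 0:
            data[s] += _draw_noise(rng, noise, smoother, n_times, sfreq)
    data -= data.mean(axis=1, keepdims=True)  # average reference
    return ErpDataset(
        data=data,
        sfreq=sfreq,
        window_ms=epoch_window_ms,
        montage=montage,
        subject_ids=covariate.subject_ids,
    )


def calibrate_gain(
    target_corr: float,
    template: np.ndarray,
    noise_sd_uv: float,
    covariate_sd: float = DPRIME_SD,
) -> float:
    """Covariate gain (µV per unit d') giving a chosen per-electrode
    voltage-vs-covariate Pearson correlation at the template's peak
    electrode, at the envelope peak, for independent channel noise of the
    given SD.

    Solves |rho| = g*sd_u*|T_peak| / sqrt(g^2 sd_u^2 T_peak^2 + sd_noise^2).
    """
    if not 0 < target_corr < 1:
        raise ValueError("target_corr must lie in (0, 1)")
    t_peak = float(np.max(np.abs(template)))
    return (
        target_corr
        * noise_sd_uv
        / (np.sqrt(1.0 - target_corr**2) * covariate_sd * t_peak)
    )


def default_study_components(montage: Montage, noise_sd_uv: float = 1.0):
    """The two covariate-linked components emulating the study's effects,
    plus covariate-independent background activity.

    * an occipital-positive / central-negative difference pattern at
      126-148 ms whose topographic expression scales with d' (P1-like),
    * a centroparietal-positive / frontal-negative pattern at 530-638 ms
      whose amplitude (hence GFP) and topography scale with d' (P3b-like),
    * background evoked activity spanning the epoch so that normalized-map
      analyses have a covariate-independent reference topography.

    The covariate-linked templates are deliberately distinct from the
    concurrent background topography: a covariate that merely rescaled the
    background map would be invisible to shape analyses on GFP=1 maps.
    Covariate-linked components use flat (boxcar) envelopes so their stated
    latency window is their full-strength support; gains are calibrated for
    a per-electrode voltage-d' correlation of about 0.6 at the template
    peak.
    """
    occ = topographic_template(montage, "Oz", fwhm_deg=70.0)
    frontal = topographic_template(montage, "Fz", fwhm_deg=75.0)
    # early shape-only pattern: occipital-positive / central-negative,
    # orthogonalized against the concurrent background directions so its
    # covariate link changes map shape rather than overall field strength
    early_raw = occ - topographic_template(montage, "Cz", fwhm_deg=80.0)
    for bg in (frontal, occ):
        early_raw = early_raw - (early_raw @ bg) / (bg @ bg) * bg
    early = normalize_template(early_raw)
    # late pattern: centroparietal-positive / frontal-negative. Built as a
    # controlled mix of a shape part orthogonal to the sustained background
    # (drives the topographic link) and a part aligned with it (drives the
    # global-field-power link), so the component is genuinely
    # amplitude-and-topography-linked.
    bg_dir = normalize_template(-frontal)
    late_raw = (
        topographic_template(montage, "CPz", fwhm_deg=80.0)
        - topographic_template(montage, "Fz", fwhm_deg=80.0)
    )
    late_orth = normalize_template(
        late_raw - (late_raw @ bg_dir) / (bg_dir @ bg_dir) * bg_dir
    )
    late = normalize_template(late_orth + 0.25 * bg_dir)
    g_early = calibrate_gain(0.6, early, noise_sd_uv)
    g_late = calibrate_gain(0.6, late, noise_sd_uv)
    return [
        # covariate-independent background: sustained frontal negativity
        # keeping topographies consistent across the whole epoch, plus an
        # occipital evoked deflection
        ComponentSpec(
            -100.0, 1000.0, frontal, base_amplitude=-1.5, covariate_gain=0.0,
            temporal_envelope="boxcar",
        ),
        ComponentSpec(60.0, 300.0, occ, base_amplitude=2.0, covariate_gain=0.0),
        # topography-linked early component
        ComponentSpec(
            126.0, 148.0, early, base_amplitude=0.5, covariate_gain=g_early,
            temporal_envelope="boxcar",
        ),
        # amplitude-and-topography-linked late component
        ComponentSpec(
            530.0, 638.0, late, base_amplitude=0.5, covariate_gain=g_late,
            temporal_envelope="boxcar",
        ),
    ]


def simulate_study_like_dataset(
    montage: Montage,
    n_subjects: int = 38,
    noise_sd_uv: float = 1.0,
    seed=None,
) -> tuple[ErpDataset, CovariateSeries, list[ComponentSpec]]:
    """Full study-scale synthetic dataset: 38 subjects, 512 Hz, -100..1000 ms,
    with the default covariate-linked components."""
    rng = np.random.default_rng(seed)
    covariate = sample_dprime_covariate(n_subjects, seed=rng.integers(2**31))
    components = default_study_components(montage, noise_sd_uv)
    erps = simulate_erp_dataset(
        n_subjects,
        montage,
        components,
        NoiseSpec(sd_uv=noise_sd_uv),
        covariate,
        seed=rng.integers(2**31),
    )
    return erps, covariate, components


def simulate_subject_epochs(
    montage: Montage,
    components: list[ComponentSpec],
    dprime_value: float,
    n_epochs: int,
    noise: NoiseSpec,
    sfreq: float = 512.0,
    epoch_window_ms: tuple[float, float] = (-100.0, 1000.0),
    seed=None,
) -> np.ndarray:
    """Single-trial epochs (epochs x channels x times) for one subject; the
    across-epoch mean converges to the subject's model ERP. Off the default
    path (cohort synthesis produces subject averages directly) but useful to
    exercise epoch rejection and averaging."""
    rng = np.random.default_rng(seed)
    n_times = int(round((epoch_window_ms[1] - epoch_window_ms[0]) / 1000.0 * sfreq))
    times = epoch_window_ms[0] + np.arange(n_times) * 1000.0 / sfreq
    smoother = _spatial_smoother(montage, noise.spatial_fwhm_deg)
    signal = np.zeros((montage.n_channels, n_times))
    for comp in components:
        amp = comp.base_amplitude + comp.covariate_gain * dprime_value
        signal += amp * np.outer(comp.template, comp.envelope(times))
    out = np.empty((n_epochs, montage.n_channels, n_times))
    for e in range(n_epochs):
        out[e] = signal + _draw_noise(rng, noise, smoother, n_times, sfreq)
    return out
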