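"""Synthetic observers, components, noise and dataset generation."""

import numpy as np
import pytest
from scipy.stats import norm

from topolearn.behavior import dprime, tabulate

from topolearn.synth import (
    ComponentSpec,
    NoiseSpec,
    ObserverSpec,
    calibrate_gain,
    normalize_template,
    sample_dprime_covariate,
    simulate_erp_dataset,
    simulate_subject_epochs,
    simulate_trials,
    topographic_template,
)


class TestSimulateTrials:
    def test_zero_sensitivity_symmetry(self):
        obs = ObserverSpec(0.0, 0.0, 100_000, 100_000)
        counts = tabulate(simulate_trials(obs, seed=1))
        assert counts.hit / counts.n_targets == pytest.approx(0.5, abs=0.01)
        assert counts.fa / counts.n_lures == pytest.approx(0.5, abs=0.01)

    def test_rates_match_closed_form(self):
        # d'=2, c=1: HR -> Phi(1), FAR -> Phi(-1)
        obs = ObserverSpec(2.0, 1.0, 200_000, 200_000)
        counts = tabulate(simulate_trials(obs, seed=2))
        assert counts.hit / counts.n_targets == pytest.approx(norm.cdf(1.0), abs=0.005)
        assert counts.fa / counts.n_lures == pytest.approx(norm.cdf(-1.0), abs=0.005)

    def test_all_timeouts_empty_counts(self):
        obs = ObserverSpec(1.0, 0.5, 50, 50, timeout_rate=1.0)
        counts = tabulate(simulate_trials(obs, seed=3))
        assert counts.total == 0

    def test_trial_count_conserved(self):
        obs = ObserverSpec(1.0, 0.5, 300, 200, timeout_rate=0.1)
        log = simulate_trials(obs, seed=4)
        counts = tabulate(log)
        n_timeouts = int((log["response"] == "timeout").sum())
        assert counts.total + n_timeouts == 500

    def test_seed_reproducibility(self):
        obs = ObserverSpec(1.5, 0.7, 100, 100, timeout_rate=0.05)
        a, b = simulate_trials(obs, seed=7), simulate_trials(obs, seed=7)
        assert a.equals(b)

    def test_parameter_recovery(self):
        # dprime(tabulate(simulate)) -> theta as n grows
        obs = ObserverSpec(1.19, 0.6, 100_000, 100_000)
        est = dprime(tabulate(simulate_trials(obs, seed=8)))
        assert est == pytest.approx(1.19, abs=0.03)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ObserverSpec(1.0, 0.0, -1, 10)
        with pytest.raises(ValueError):
            ObserverSpec(1.0, 0.0, 10, 10, timeout_rate=1.5)


class TestTemplatesAndEnvelopes:
    def test_template_zero_mean_unit_gfp(self, montage64):
        t = topographic_template(montage64, "Oz")
        assert abs(t.mean()) < 1e-12
        assert np.sqrt(np.mean(t**2)) == pytest.approx(1.0)
        assert np.argmax(t) == montage64.index("Oz")

    def test_normalize_template_rejects_constant(self):
        with pytest.raises(ValueError):
            normalize_template(np.ones(8))

    @pytest.mark.parametrize("shape", ["tukey", "hann", "boxcar"])
    def test_envelope_support(self, montage64, shape):
        tmpl = topographic_template(montage64, "Cz")
        comp = ComponentSpec(100.0, 200.0, tmpl, temporal_envelope=shape)
        t = np.linspace(-100, 1000, 2000)
        env = comp.envelope(t)
        inside = (t >= 100) & (t < 200)
        assert np.all(env[~inside] == 0.0)
        assert env.max() == pytest.approx(1.0, abs=1e-3)
        # full amplitude at mid-window for every shape
        assert comp.envelope(np.array([150.0]))[0] == pytest.approx(1.0, abs=1e-6)

    def test_component_window_validation(self, montage64):
        tmpl = topographic_template(montage64, "Cz")
        with pytest.raises(ValueError):
            ComponentSpec(200.0, 100.0, tmpl)
        with pytest.raises(ValueError):
            ComponentSpec(0.0, 100.0, tmpl * 2.0)  # not unit GFP


class TestSimulateErpDataset:
    def _one_component(self, montage, gain):
        tmpl = topographic_template(montage, "Oz")
        return [ComponentSpec(100.0, 300.0, tmpl, 1.0, gain, "boxcar")]

    def test_noiseless_no_gain_identical_subjects(self, montage64):
        cov = sample_dprime_covariate(5, seed=1)
        erps = simulate_erp_dataset(
            5, montage64, self._one_component(montage64, 0.0), NoiseSpec(0.0),
            cov, seed=2,
        )
        t = erps.times_ms
        inside = (t >= 100) & (t < 300)
        assert np.allclose(erps.data[:, :, ~inside], 0.0)
        for s in range(1, 5):
            assert np.allclose(erps.data[s], erps.data[0])
        assert np.abs(erps.data[:, :, inside]).max() > 0

    def test_noiseless_gain_perfect_correlation(self, montage64):
        cov = sample_dprime_covariate(8, seed=3)
        erps = simulate_erp_dataset(
            8, montage64, self._one_component(montage64, 0.5), NoiseSpec(0.0),
            cov, seed=4,
        )
        ti = erps.time_index(200.0)
        tmpl = self._one_component(montage64, 0.5)[0].template
        for c in np.flatnonzero(np.abs(tmpl) > 1e-6):
            r = np.corrcoef(erps.data[:, c, ti], cov.values)[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_average_reference_invariant(self, montage64):
        cov = sample_dprime_covariate(6, seed=5)
        erps = simulate_erp_dataset(
            6, montage64, self._one_component(montage64, 0.3), NoiseSpec(1.0),
            cov, seed=6,
        )
        assert erps.is_average_referenced()

    def test_seed_reproducibility(self, montage64):
        cov = sample_dprime_covariate(4, seed=7)
        kwargs = dict(
            n_subjects=4,
            montage=montage64,
            components=self._one_component(montage64, 0.3),
            noise=NoiseSpec(1.0),
            covariate=cov,
        )
        a = simulate_erp_dataset(seed=11, **kwargs)
        b = simulate_erp_dataset(seed=11, **kwargs)
        assert np.array_equal(a.data, b.data)

    def test_component_outside_epoch_rejected(self, montage64):
        tmpl = topographic_template(montage64, "Oz")
        cov = sample_dprime_covariate(4, seed=8)
        with pytest.raises(ValueError):
            simulate_erp_dataset(
                4, montage64, [ComponentSpec(-200.0, 100.0, tmpl)],
                NoiseSpec(1.0), cov, seed=9,
            )

    def test_covariate_length_checked(self, montage64):
        cov = sample_dprime_covariate(3, seed=10)
        with pytest.raises(ValueError):
            simulate_erp_dataset(
                5, montage64, self._one_component(montage64, 0.0),
                NoiseSpec(1.0), cov, seed=11,
            )


class TestCovariateSampler:
    def test_respects_bounds_and_moments(self):
        cov = sample_dprime_covariate(5000, seed=12)
        assert cov.values.min() >= -0.09
        assert cov.values.max() <= 2.32
        assert cov.values.mean() == pytest.approx(1.19, abs=0.05)
        assert cov.values.std() == pytest.approx(0.51, abs=0.05)

    def test_calibrated_gain_hits_target_correlation(self, montage64):
        tmpl = topographic_template(montage64, "Oz")
        gain = calibrate_gain(0.6, tmpl, noise_sd_uv=1.0)
        cov = sample_dprime_covariate(4000, seed=13)
        comps = [ComponentSpec(100.0, 300.0, tmpl, 0.5, gain, "boxcar")]
        erps = simulate_erp_dataset(
            4000, montage64, comps, NoiseSpec(1.0, spatial_fwhm_deg=0.0,
                                              temporal_fwhm_ms=0.0),
            cov, sfreq=64.0, epoch_window_ms=(0.0, 400.0), seed=14,
        )
        ti = erps.time_index(200.0)
        peak = int(np.argmax(np.abs(tmpl)))
        r = np.corrcoef(erps.data[:, peak, ti], cov.values)[0, 1]
        assert abs(r) == pytest.approx(0.6, abs=0.05)


def test_subject_epochs_average_to_model_erp(montage64):
    tmpl = topographic_template(montage64, "Cz")
    comps = [ComponentSpec(100.0, 300.0, tmpl, 2.0, 0.0, "boxcar")]
    epochs = simulate_subject_epochs(
        montage64, comps, dprime_value=1.0, n_epochs=400,
        noise=NoiseSpec(1.0), sfreq=128.0, epoch_window_ms=(0.0, 400.0), seed=15,
    )
    mean = epochs.mean(axis=0)
    times = np.arange(mean.shape[1]) * 1000.0 / 128.0
    ti = int(np.argmin(np.abs(times - 200.0)))
    assert np.corrcoef(mean[:, ti], tmpl)[0, 1] > 0.97
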