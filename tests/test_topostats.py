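"""GFP, covariance maps, the randomization tests and window logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topolearn.datasets import CovariateSeries, ErpDataset
from topolearn.synth import (
    ComponentSpec,
    NoiseSpec,
    sample_dprime_covariate,
    simulate_erp_dataset,
    topographic_template,
)
from topolearn.topostats import (
    CovarianceMap,
    RandomizationResult,
    covariance_map,
    gfp,
    gfp_covariation,
    normalize_gfp,
    significant_windows,
    spatial_correlation,
    subdivide_and_merge,
    tancova,
    tct,
    window_covariance_map,
)


class TestGfp:
    def test_hand_computed_values(self):
        assert gfp(np.zeros(4)) == 0.0
        assert gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)
        assert gfp(np.array([2.0, 0.0, -2.0, 0.0])) == pytest.approx(np.sqrt(2.0))

    def test_matches_population_sd_for_zero_mean(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(32)
        v -= v.mean()
        assert gfp(v) == pytest.approx(np.std(v))

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_normalize_scale_invariance(self, scale):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(16)
        a = normalize_gfp(v)
        b = normalize_gfp(v * scale)
        assert np.allclose(a, b)
        assert gfp(a) == pytest.approx(1.0)

    def test_normalize_zero_map_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_gfp(np.zeros(8))


class TestCovarianceMap:
    def test_constant_covariate_zero_map(self, make_erps, make_covariate):
        erps = make_erps(n_subjects=6)
        u = make_covariate(erps.subject_ids, values=np.full(6, 2.5))
        cmap = covariance_map(erps, u, t_ms=10.0)
        assert np.allclose(cmap.values, 0.0)

    def test_matches_independent_per_electrode_covariance(
        self, make_erps, make_covariate
    ):
        erps = make_erps(n_subjects=9, seed=3)
        u = make_covariate(erps.subject_ids, seed=4)
        cmap = covariance_map(erps, u, t_ms=5.0)
        ti = erps.time_index(5.0)
        expected = np.array(
            [
                np.cov(erps.data[:, c, ti], u.values)[0, 1]
                for c in range(erps.n_channels)
            ]
        )
        assert np.allclose(cmap.values, expected)

    def test_noiseless_map_recovers_template(self, montage64):
        tmpl = topographic_template(montage64, "Oz")
        comps = [ComponentSpec(100.0, 300.0, tmpl, 1.0, 0.7, "boxcar")]
        cov = sample_dprime_covariate(10, seed=5)
        erps = simulate_erp_dataset(10, montage64, comps, NoiseSpec(0.0), cov, seed=6)
        cmap = covariance_map(erps, cov, t_ms=200.0)
        r = spatial_correlation(
            CovarianceMap(normalize_gfp(cmap.values)), CovarianceMap(tmpl)
        )
        assert abs(r) >= 0.999999
        # V proportional to gain * var(u) * template
        expected = 0.7 * np.var(cov.values, ddof=1) * tmpl
        assert np.allclose(cmap.values, expected)

    def test_joint_permutation_invariance(self, make_erps, make_covariate):
        erps = make_erps(n_subjects=7, seed=7)
        u = make_covariate(erps.subject_ids, seed=8)
        perm = np.random.default_rng(9).permutation(7)
        erps_p = ErpDataset(
            erps.data[perm], erps.sfreq, erps.window_ms, erps.montage,
            tuple(erps.subject_ids[i] for i in perm),
        )
        u_p = CovariateSeries(erps_p.subject_ids, u.values[perm])
        a = covariance_map(erps, u, 5.0)
        b = covariance_map(erps_p, u_p, 5.0)
        assert np.allclose(a.values, b.values)

    def test_linearity_in_covariate(self, make_erps, make_covariate):
        erps = make_erps(n_subjects=8, seed=10)
        u1 = make_covariate(erps.subject_ids, seed=11)
        u2 = make_covariate(erps.subject_ids, seed=12)
        u12 = make_covariate(erps.subject_ids, values=u1.values + u2.values)
        v1 = covariance_map(erps, u1, 5.0).values
        v2 = covariance_map(erps, u2, 5.0).values
        v12 = covariance_map(erps, u12, 5.0).values
        assert np.allclose(v12, v1 + v2)

    def test_too_few_subjects(self, make_erps, make_covariate):
        erps = make_erps(n_subjects=2)
        u = make_covariate(erps.subject_ids)
        with pytest.raises(ValueError):
            covariance_map(erps, u, 5.0)


class TestSpatialCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(13)
        m = CovarianceMap(rng.standard_normal(16))
        assert spatial_correlation(m, m) == pytest.approx(1.0)
        assert spatial_correlation(m, CovarianceMap(-m.values)) == pytest.approx(-1.0)

    def test_orthogonal_patterns(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert spatial_correlation(CovarianceMap(a), CovarianceMap(b)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(
                CovarianceMap(np.ones(4)), CovarianceMap(np.arange(4.0))
            )


class TestTancova:
    def test_null_p_values_super_uniform(self, make_erps, make_covariate):
        # pure-noise data, covariate independent: rejection at alpha must
        # not exceed alpha beyond Monte-Carlo error
        hits, total = 0, 0
        for rep in range(60):
            erps = make_erps(n_subjects=8, n_times=12, seed=100 + rep)
            u = make_covariate(erps.subject_ids, seed=200 + rep)
            res = tancova(erps, u, n_perm=200, seed=300 + rep, allow_small=False)
            hits += int(res.significant(0.05).sum())
            total += res.p.size
        rate = hits / total
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_scale_invariance_per_subject(self, make_erps, make_covariate):
        # normalized-map TANCOVA ignores per-subject global rescaling
        erps = make_erps(n_subjects=8, n_times=10, seed=14)
        u = make_covariate(erps.subject_ids, seed=15)
        scales = np.random.default_rng(16).uniform(0.5, 5.0, 8)
        scaled = ErpDataset(
            erps.data * scales[:, None, None], erps.sfreq, erps.window_ms,
            erps.montage, erps.subject_ids,
        )
        a = tancova(erps, u, n_perm=200, seed=17, allow_small=False)
        b = tancova(scaled, u, n_perm=200, seed=17, allow_small=False)
        assert np.allclose(a.p, b.p)
        assert np.allclose(a.effect, b.effect)

    def test_seed_determinism(self, make_erps, make_covariate):
        erps = make_erps(n_subjects=6, n_times=8, seed=18)
        u = make_covariate(erps.subject_ids, seed=19)
        a = tancova(erps, u, n_perm=300, seed=20)
        b = tancova(erps, u, n_perm=300, seed=20)
        assert np.array_equal(a.p, b.p)

    def test_small_n_perm_rejected(self, make_erps, make_covariate):
        erps = make_erps()
        u = make_covariate(erps.subject_ids)
        with pytest.raises(ValueError):
            tancova(erps, u, n_perm=50)
        tancova(erps, u, n_perm=50, allow_small=True)  # explicit override

    def test_frames_restriction_sets_nan(self, make_erps, make_covariate):
        erps = make_erps(n_times=10)
        u = make_covariate(erps.subject_ids)
        frames = np.zeros(10, bool)
        frames[3:7] = True
        res = tancova(erps, u, n_perm=200, seed=21, frames=frames)
        assert np.isnan(res.p[~frames]).all()
        assert np.isfinite(res.p[frames]).all()


class TestTct:
    def test_shared_map_maximally_consistent(self, montage16, make_covariate):
        rng = np.random.default_rng(22)
        shared = rng.standard_normal(16)
        shared -= shared.mean()
        data = np.tile(shared[None, :, None], (10, 1, 6))
        erps = ErpDataset(
            data, 512.0, (0.0, 6 * 1000 / 512.0), montage16,
            tuple(f"S{i}" for i in range(10)),
        )
        res = tct(erps, n_perm=300, seed=23)
        assert np.all(res.p <= 2.0 / 301.0)

    def test_null_calibration(self, make_erps):
        hits, total = 0, 0
        for rep in range(40):
            erps = make_erps(n_subjects=8, n_times=10, seed=400 + rep)
            res = tct(erps, n_perm=200, seed=500 + rep)
            hits += int(res.significant(0.05).sum())
            total += res.p.size
        rate = hits / total
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_single_subject_degenerates(self, make_erps):
        erps = make_erps(n_subjects=1)
        res = tct(erps, n_perm=200, seed=24)
        assert np.isnan(res.p).all()
        subj_gfp = np.sqrt(np.mean(erps.data[0] ** 2, axis=0))
        assert np.allclose(res.effect, subj_gfp)


class TestGfpCovariation:
    def test_constant_covariate_never_significant(self, make_erps, make_covariate):
        erps = make_erps(n_subjects=8, n_times=10, seed=25)
        u = make_covariate(erps.subject_ids, values=np.full(8, 1.19))
        res = gfp_covariation(erps, u, n_perm=200, seed=26)
        assert not res.significant(0.05).any()
        assert np.allclose(res.effect, 0.0)

    def test_amplitude_link_dissociates_from_topography(self, montage64):
        # component amplitude scales with u while normalized topography is
        # unchanged: GFP covariation fires, normalized-map TANCOVA does not
        tmpl = topographic_template(montage64, "Cz")
        comps = [ComponentSpec(0.0, 200.0, tmpl, 1.0, 2.0, "boxcar")]
        cov = sample_dprime_covariate(24, seed=27)
        erps = simulate_erp_dataset(
            24, montage64, comps, NoiseSpec(0.0), cov,
            sfreq=128.0, epoch_window_ms=(0.0, 200.0), seed=28,
        )
        g = gfp_covariation(erps, cov, n_perm=500, seed=29)
        t = tancova(erps, cov, n_perm=500, seed=30)
        assert np.all(g.p < 0.05)
        # identical normalized maps across subjects: zero effect under
        # normalization, never significant
        assert np.allclose(t.effect, 0.0, atol=1e-12)
        assert not t.significant(0.05).any()

    def test_permutation_rank_invariance_under_scaling(
        self, make_erps, make_covariate
    ):
        erps = make_erps(n_subjects=8, n_times=10, seed=31)
        u = make_covariate(erps.subject_ids, seed=32)
        doubled = ErpDataset(
            2.0 * erps.data, erps.sfreq, erps.window_ms, erps.montage,
            erps.subject_ids,
        )
        a = gfp_covariation(erps, u, n_perm=300, seed=33)
        b = gfp_covariation(doubled, u, n_perm=300, seed=33)
        assert np.allclose(b.effect, 2.0 * a.effect)
        assert np.allclose(a.p, b.p)


class TestSignificanceWindows:
    def _result(self, p, sfreq=512.0):
        n = len(p)
        return RandomizationResult(
            times_ms=np.arange(n) * 1000.0 / sfreq,
            effect=np.ones(n),
            p=np.asarray(p, float),
            n_perm=1000,
            seed=0,
            sfreq=sfreq,
        )

    def test_all_nonsignificant_empty(self):
        assert len(significant_windows(self._result(np.ones(50)))) == 0

    def test_short_run_excluded(self):
        # 8 frames at 512 Hz ~ 15.6 ms < 20 ms: dropped
        p = np.ones(60)
        p[20:28] = 0.001
        assert len(significant_windows(self._result(p))) == 0

    def test_minimum_duration_run_retained(self):
        # 11 frames = ceil(20 ms * 512 / 1000): retained
        p = np.ones(60)
        p[20:31] = 0.001
        wins = significant_windows(self._result(p))
        assert len(wins) == 1
        (start, end), = wins.windows
        assert end - start == pytest.approx(11 * 1000.0 / 512.0)

    def test_everything_significant_single_window(self):
        p = np.full(60, 0.001)
        wins = significant_windows(self._result(p))
        assert len(wins) == 1
        assert wins.windows[0][0] == 0.0

    def test_nan_breaks_runs(self):
        p = np.full(40, 0.001)
        p[15:20] = np.nan
        wins = significant_windows(self._result(p))
        assert len(wins) == 2


@pytest.fixture
def high_snr(montage64):
    def build(second_center):
        occ = topographic_template(montage64, "Oz", 70.0)
        second = topographic_template(montage64, second_center, 60.0)
        frontal = topographic_template(montage64, "Fz", 75.0)
        comps = [
            ComponentSpec(-100.0, 1000.0, frontal, -1.5, 0.0, "boxcar"),
            ComponentSpec(300.0, 520.0, occ, 0.2, 2.0, "hann"),
            ComponentSpec(420.0, 640.0, second, 0.2, 2.0, "hann"),
        ]
        cov = sample_dprime_covariate(38, seed=3)
        erps = simulate_erp_dataset(38, montage64, comps, NoiseSpec(0.05), cov, seed=4)
        res = tancova(erps, cov, n_perm=500, seed=5)
        win = list(significant_windows(res))[0]
        return res, erps, cov, win

    return build


class TestSubdivideAndMerge:
    def test_two_templates_stay_separate(self, high_snr):
        res, erps, cov, win = high_snr("C3")
        items = subdivide_and_merge(res, erps, cov, win)
        assert len(items) == 2
        r = spatial_correlation(items[0][1], items[1][1])
        assert r < 0.7

    def test_single_template_merges_fully(self, high_snr):
        res, erps, cov, win = high_snr("Oz")
        items = subdivide_and_merge(res, erps, cov, win)
        assert len(items) == 1

    def test_short_window_returned_whole(self, make_erps, make_covariate):
        erps = make_erps(n_subjects=8, n_times=20, seed=34)
        u = make_covariate(erps.subject_ids, seed=35)
        res = tancova(erps, u, n_perm=200, seed=36)
        win = (0.0, 30.0)  # 30 ms < 70 ms
        items = subdivide_and_merge(res, erps, u, win)
        assert len(items) == 1
        assert items[0][0] == win

    def test_window_map_is_time_average(self, make_erps, make_covariate):
        erps = make_erps(n_subjects=8, n_times=20, seed=37)
        u = make_covariate(erps.subject_ids, seed=38)
        win = (0.0, 20.0)
        cmap = window_covariance_map(erps, u, win)
        times = erps.times_ms
        sel = (times >= win[0]) & (times < win[1])
        per_frame = np.stack(
            [covariance_map(erps, u, t).values for t in times[sel]]
        )
        assert np.allclose(cmap.values, per_frame.mean(axis=0))


class TestExhaustivePermutationAgreement:
    def test_monte_carlo_matches_enumeration(self, make_erps, make_covariate):
        """For n=6 subjects the Monte-Carlo p must agree with the exhaustive
        720-permutation p within binomial error at every frame."""
        from itertools import permutations

        erps = make_erps(n_subjects=6, n_times=10, seed=39)
        u = make_covariate(erps.subject_ids, seed=40)
        res = tancova(erps, u, n_perm=4000, seed=41)

        # independent exhaustive oracle
        X = erps.data.copy()
        g = np.sqrt(np.mean(X**2, axis=1))
        X = X / g[:, None, :]
        Xc = X - X.mean(axis=0, keepdims=True)
        uc = u.values - u.values.mean()
        obs = np.sqrt(np.mean(np.einsum("sct,s->ct", Xc, uc) ** 2, axis=0))
        exact = np.zeros(10)
        for perm in permutations(range(6)):
            v = np.einsum("sct,s->ct", Xc, uc[list(perm)])
            eff = np.sqrt(np.mean(v**2, axis=0))
            exact += eff >= obs - 1e-12
        exact /= 720.0

        se = np.sqrt(exact * (1 - exact) / res.n_perm)
        assert np.all(np.abs(res.p - exact) <= 3 * se + 1.0 / (res.n_perm + 1))
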