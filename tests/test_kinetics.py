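"""dM% curves, exponential-rise fits and semi-log consumption slopes."""

import numpy as np
import pytest
from scipy import stats

from toldmri import (DmCurve, GasInterval, GasSchedule, ToldSeries,
                     compute_dm_percent, fit_consumption, fit_oxygenation,
                     make_brain_phantom, make_told_series, map_told,
                     told_response)
from toldmri import reference as ref


def _flat_series(value=100.0, n=18):
    sched = ref.standard_challenge_schedule()
    times = np.arange(n) / 3.0
    data = np.full((2, 2, n), value)
    return ToldSeries(data, times, sched)


def _rise_curve(s_max=5.18, k_ox=1.69, onset=5.0, dt=1 / 3, n=45, k_oc=1.55):
    times = np.arange(n) * dt
    vals = told_response(times, [(onset, 10.0)], s_max, 1.0 / k_ox, k_oc)
    return DmCurve(times, vals)


class TestComputeDmPercent:
    def test_constant_series_gives_zero(self):
        curve = compute_dm_percent(_flat_series(), np.ones((2, 2), bool))
        np.testing.assert_array_equal(curve.dm_percent, 0.0)

    def test_five_percent_enhancement(self):
        s = _flat_series()
        s.data[..., -1] = 105.0
        curve = compute_dm_percent(s, np.ones((2, 2), bool))
        assert curve.dm_percent[-1] == pytest.approx(5.0, rel=1e-12)

    def test_baseline_mean_is_zero(self, noiseless_told, brain_scene):
        series, _ = noiseless_told
        mask = brain_scene.region("cortex").mask(brain_scene.grid_shape)
        curve = compute_dm_percent(series, mask)
        assert curve.dm_percent[series.baseline_frames].mean() == pytest.approx(0.0, abs=1e-12)

    def test_matches_generator_ground_truth(self, noiseless_told, brain_scene):
        series, truth = noiseless_told
        row = truth[truth.roi == "cortex"].iloc[0]
        mask = brain_scene.region("cortex").mask(brain_scene.grid_shape)
        curve = compute_dm_percent(series, mask)
        expected = told_response(series.frame_times_min, [(5.0, 10.0)],
                                 row.s_max, row.t_ox_min, row.k_oc_per_min)
        np.testing.assert_allclose(curve.dm_percent, expected, atol=1e-10)

    def test_scale_invariance(self, noiseless_told, brain_scene):
        series, _ = noiseless_told
        mask = brain_scene.region("cortex").mask(brain_scene.grid_shape)
        a = compute_dm_percent(series, mask)
        scaled = ToldSeries(series.data * 17.3, series.frame_times_min,
                            series.schedule, baseline_frames=series.baseline_frames)
        b = compute_dm_percent(scaled, mask)
        np.testing.assert_allclose(a.dm_percent, b.dm_percent, atol=1e-10)

    def test_pixel_mode(self, noiseless_told):
        series, _ = noiseless_told
        curve = compute_dm_percent(series, (32, 32))
        assert curve.source == "pixel(32, 32)"
        assert curve.dm_percent.shape == series.frame_times_min.shape

    def test_nonpositive_baseline_rejected(self):
        s = _flat_series(0.0)
        with pytest.raises(ValueError, match="baseline"):
            compute_dm_percent(s, np.ones((2, 2), bool))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_dm_percent(_flat_series(), np.zeros((2, 2), bool))


class TestFitOxygenation:
    def test_noiseless_recovery_of_cortex_parameters(self):
        curve = _rise_curve()
        fit = fit_oxygenation(curve, 5.0, 10.0)
        assert fit.converged
        assert fit.s_max == pytest.approx(5.18, rel=1e-4)
        assert fit.k_ox_per_min == pytest.approx(1.69, rel=1e-4)

    def test_kox_tox_reciprocal_exactly(self):
        fit = fit_oxygenation(_rise_curve(), 5.0, 10.0)
        assert fit.k_ox_per_min == 1.0 / fit.t_ox_min

    def test_curve_reaches_63_percent_at_tox(self):
        fit = fit_oxygenation(_rise_curve(), 5.0, 10.0)
        val = told_response(5.0 + fit.t_ox_min, [(5.0, 10.0)], 5.18, 1 / 1.69, 1.55)
        assert val == pytest.approx((1 - np.exp(-1)) * fit.s_max, rel=1e-6)

    def test_flat_curve_flagged_degenerate(self):
        curve = DmCurve(np.arange(10) / 3.0 + 5.0, np.zeros(10))
        fit = fit_oxygenation(curve, 5.0, 8.0)
        assert fit.s_max == 0.0 and not fit.converged

    def test_too_few_frames_rejected(self):
        curve = DmCurve(np.array([5.0, 5.5, 6.0]), np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError, match="at least 4"):
            fit_oxygenation(curve, 5.0, 6.0)

    def test_negative_response_fitted(self):
        curve = _rise_curve(s_max=-4.0, k_ox=0.63)
        fit = fit_oxygenation(curve, 5.0, 10.0)
        assert fit.s_max == pytest.approx(-4.0, rel=1e-4)


class TestFitConsumption:
    def test_exact_decay_recovers_koc(self):
        t = np.arange(36) / 3.0
        vals = 5.0 * np.exp(-1.55 * np.clip(t - 10.0, 0, None)) * (t >= 10.0)
        vals[t < 10.0] = 5.0
        curve = DmCurve(t, vals)
        fit = fit_consumption(curve, 10.0, 5)
        assert fit.k_oc_per_min == pytest.approx(1.55, rel=1e-10)
        assert fit.n_points == 5

    def test_constant_positive_curve_gives_zero_rate(self):
        curve = DmCurve(np.arange(12) / 3.0, np.full(12, 3.0))
        assert fit_consumption(curve, 1.0, 5).k_oc_per_min == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_slope_oracle(self):
        rng = np.random.default_rng(3)
        t = 10.0 + np.arange(1, 9) / 3.0
        vals = 5.0 * np.exp(-1.2 * (t - 10.0)) * np.exp(rng.normal(0, 0.05, t.size))
        curve = DmCurve(t, vals)
        fit = fit_consumption(curve, 10.0, 8)
        lr = stats.linregress(t, np.log(vals))
        assert fit.k_oc_per_min == pytest.approx(-lr.slope, rel=1e-12)

    def test_nonpositive_points_excluded_and_counted(self):
        t = 10.0 + np.arange(1, 7) / 3.0
        vals = np.array([3.0, -0.1, 1.0, 0.5, 0.2, 0.1])
        fit = fit_consumption(DmCurve(t, vals), 10.0, 5)
        assert fit.n_excluded == 1 and fit.n_points == 5

    def test_too_few_positive_points_rejected(self):
        curve = DmCurve(np.array([10.5, 11.0, 11.5]), np.array([1.0, -1.0, -2.0]))
        with pytest.raises(ValueError, match="positive"):
            fit_consumption(curve, 10.0, 5)

    def test_noisy_decay_median_recovery(self):
        """Median k_oc over seeds is within 10% of truth at 2% noise."""
        rng = np.random.default_rng(21)
        t = 10.0 + np.arange(1, 6) / 3.0
        clean = 5.18 * np.exp(-1.55 * (t - 10.0))
        est = []
        for _ in range(12):
            vals = clean + rng.normal(0, 0.02 * 5.18, t.size)
            est.append(fit_consumption(DmCurve(t, vals), 10.0, 5).k_oc_per_min)
        assert np.median(est) == pytest.approx(1.55, rel=0.10)


class TestPipelineRecovery:
    def test_noiseless_full_round_trip(self, noiseless_told, brain_scene):
        """simulate -> dM% -> fits reproduces the generator parameter table."""
        series, truth = noiseless_told
        for _, row in truth.iterrows():
            mask = brain_scene.region(row.roi).mask(brain_scene.grid_shape)
            curve = compute_dm_percent(series, mask)
            rise = fit_oxygenation(curve, 5.0, 10.0)
            decay = fit_consumption(curve, 10.0, 5)
            assert rise.s_max == pytest.approx(row.s_max, rel=1e-4)
            assert rise.k_ox_per_min == pytest.approx(row.k_ox_per_min, rel=1e-4)
            assert decay.k_oc_per_min == pytest.approx(row.k_oc_per_min, rel=1e-4)

    def test_noisy_median_unbiased(self, brain_scene, challenge_schedule):
        """At 1% noise, cortex parameter medians over 20 seeds are within 5%."""
        k_ox, s_max, k_oc = [], [], []
        mask = brain_scene.region("cortex").mask(brain_scene.grid_shape)
        for seed in range(20):
            series, _ = make_told_series(brain_scene, challenge_schedule, 20.0, 45,
                                         seed=seed, noise_sigma=0.01)
            curve = compute_dm_percent(series, mask)
            rise = fit_oxygenation(curve, 5.0, 10.0)
            k_ox.append(rise.k_ox_per_min)
            s_max.append(rise.s_max)
            k_oc.append(fit_consumption(curve, 10.0, 5).k_oc_per_min)
        assert np.median(k_ox) == pytest.approx(1 / 0.60, rel=0.05)
        assert np.median(s_max) == pytest.approx(5.08, rel=0.05)
        assert np.median(k_oc) == pytest.approx(1.55, rel=0.05)


class TestMapTold:
    def test_plateau_map_and_background(self, brain_scene, challenge_schedule):
        series, _ = make_told_series(brain_scene, challenge_schedule, 20.0, 30,
                                     seed=0, noise_sigma=0.0)
        base = np.arange(5)
        plateau = np.arange(25, 30)  # 8.3-9.7 min: >5 rise time constants in
        m = map_told(series, base, plateau)
        cortex = brain_scene.region("cortex").mask(brain_scene.grid_shape)
        background = brain_scene.label_image() == 0
        assert m.roi_mean(cortex) == pytest.approx(5.08, abs=0.05)
        assert m.roi_mean(background) == pytest.approx(0.0, abs=1e-12)

    def test_identical_windows_give_zero(self, noiseless_told):
        series, _ = noiseless_told
        m = map_told(series, np.arange(5), np.arange(5))
        np.testing.assert_array_equal(m.values[m.valid], 0.0)

    def test_negative_plateau_maps_negative(self):
        scene = make_brain_phantom(noise_sigma=0.0)
        scene.regions[0].s_max = -3.0
        series, _ = make_told_series(scene, ref.standard_challenge_schedule(),
                                     20.0, 30, seed=0)
        m = map_told(series, np.arange(5), np.arange(25, 30))
        cortex = scene.regions[0].mask(scene.grid_shape)
        assert m.roi_mean(cortex) < 0

    def test_bad_windows_rejected(self, noiseless_told):
        series, _ = noiseless_told
        with pytest.raises(ValueError):
            map_told(series, [], [1, 2])
        with pytest.raises(ValueError, match="out of range"):
            map_told(series, [0, 1], [999])
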