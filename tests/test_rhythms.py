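"""Rhythm normalization, sinusoid/parabola fitting, and phase-shift tools."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyanoclock.phasemodel import DrivingSchedule
from cyanoclock.rhythms import (
    SinusoidFit,
    TimeSeriesTrajectory,
    dark_pulse_phase_shift,
    fit_peaks_parabolic,
    fit_sinusoid,
    fit_sinusoids_shared_period,
    kendall_entrainment_similarity,
    normalize_trajectory,
    regress_slope_with_errors,
    reject_outlier_fits,
)
from cyanoclock.synth import GroundTruth, generate_reporter_timeseries


def make_traj(t, y, light=None, **kw):
    light = np.ones_like(t, dtype=bool) if light is None else light
    return TimeSeriesTrajectory(times=np.asarray(t, float), values=np.asarray(y, float),
                                light=light, **kw)


def ld_trace(tau=12.0, T=24.0, n_cycles=3, dt=0.5):
    t = np.arange(0.0, n_cycles * T, dt)
    light = (t % T) < tau
    y = np.sin(2 * np.pi * t / T) + 100.0
    return make_traj(t, y, light)


class TestNormalize:
    def test_constant_signal_is_degenerate(self):
        traj = make_traj(np.arange(10.0), np.full(10, 7.0), series_id="flat")
        with pytest.raises(ValueError, match="flat"):
            normalize_trajectory(traj)

    def test_affine_invariance(self):
        t = np.arange(0.0, 48.0, 0.5)
        traj = make_traj(t, 3.0 * np.sin(2 * np.pi * t / 24) + 100.0)
        out = normalize_trajectory(traj)
        kept = out.values[out.mask]
        assert abs(kept.mean()) < 1e-12
        assert abs(kept.std(ddof=0) - 1.0) < 1e-12
        # shape preserved: normalized values proportional to centered input
        assert np.corrcoef(kept, traj.values[out.mask])[0, 1] > 1 - 1e-12

    def test_masking_window_sample_count(self):
        # 2.5 h window at 0.5 h cadence excludes exactly 5 samples per dawn
        traj = ld_trace(n_cycles=3)
        out = normalize_trajectory(traj, discard_after_lights_on=2.5)
        dawns = np.concatenate(([0.0], traj.dawn_times()))
        for t0 in dawns[1:]:
            in_window = (traj.times >= t0) & (traj.times < t0 + 2.5)
            assert in_window.sum() == 5
            assert not out.mask[in_window].any()
        assert not out.mask[~traj.light].any()

    def test_idempotent(self):
        traj = ld_trace()
        once = normalize_trajectory(traj)
        twice = normalize_trajectory(once)
        assert np.allclose(once.values[once.mask], twice.values[twice.mask],
                           atol=1e-12)
        assert np.array_equal(once.mask, twice.mask)


class TestSinusoidFit:
    @pytest.mark.parametrize("phi", np.linspace(0.0, 2 * np.pi, 9)[:-1])
    def test_noiseless_recovery(self, phi):
        t = np.arange(0.0, 72.5, 0.5)
        traj = make_traj(t, np.sin(2 * np.pi * t / 24 - phi))
        f = fit_sinusoid(traj, (23.0, 25.0))
        assert abs(f.amplitude - 1.0) < 1e-6
        assert abs(f.period - 24.0) < 1e-6
        want = phi if phi <= np.pi else phi - 2 * np.pi
        assert abs(f.phase - want) < 1e-6

    def test_trend_recovery(self):
        t = np.arange(0.0, 72.5, 0.5)
        traj = make_traj(t, np.sin(2 * np.pi * t / 24 - 1.0) + 0.01 * t + 2.0)
        f = fit_sinusoid(traj, (23.0, 25.0), include_trend=True)
        assert abs(f.trend - 0.01) < 1e-4
        assert abs(f.baseline - 2.0) < 1e-3
        assert abs(f.phase - 1.0) < 1e-5

    def test_fixed_period(self):
        t = np.arange(0.0, 72.5, 0.5)
        traj = make_traj(t, 2.0 * np.sin(2 * np.pi * t / 24 - 0.3))
        f = fit_sinusoid(traj, fixed_period=24.0)
        assert f.period == 24.0
        assert abs(f.amplitude - 2.0) < 1e-9
        assert f.squared_error < 1e-18

    def test_squared_error_is_residual_sum(self, rng):
        t = np.arange(0.0, 72.5, 0.5)
        y = np.sin(2 * np.pi * t / 24.3) + rng.normal(0, 0.2, t.size)
        traj = make_traj(t, y)
        f = fit_sinusoid(traj, (23.0, 25.0))
        assert np.isclose(f.squared_error, np.sum((y - f.predict(t)) ** 2))


class TestSharedPeriod:
    def test_two_noiseless_series(self):
        t = np.arange(0.0, 73.0, 0.5)
        a = make_traj(t, np.sin(2 * np.pi * t / 24.6), series_id="a")
        b = make_traj(t, np.sin(2 * np.pi * t / 24.6 - np.pi), series_id="b")
        T, fits = fit_sinusoids_shared_period([a, b], (23.0, 26.0))
        assert abs(T - 24.6) < 1e-6
        dphi = (fits[1].phase - fits[0].phase) % (2 * np.pi)
        assert abs(dphi - np.pi) < 1e-6

    def test_noisy_replicates(self, rng):
        t = np.arange(0.0, 96.25, 0.25)
        trajs = [make_traj(t, np.sin(2 * np.pi * t / 25.7 - ph)
                           + rng.normal(0, 0.2, t.size))
                 for ph in rng.uniform(0, 2 * np.pi, 10)]
        T, _ = fit_sinusoids_shared_period(trajs, (23.0, 28.0))
        assert abs(T - 25.7) < 0.1

    def test_shared_cost_optimality(self, rng):
        t = np.arange(0.0, 72.5, 0.5)
        trajs = [make_traj(t, np.sin(2 * np.pi * t / 24.4 - ph)
                           + rng.normal(0, 0.3, t.size))
                 for ph in (0.0, 1.0, 2.0)]
        T, fits = fit_sinusoids_shared_period(trajs, (23.0, 26.0))
        shared_cost = sum(f.squared_error for f in fits)
        for T_fixed in (23.5, 24.0, 25.0, 26.0):
            cost = sum(fit_sinusoid(tr, fixed_period=T_fixed).squared_error
                       for tr in trajs)
            assert shared_cost <= cost + 1e-9


class TestParabolicPeaks:
    def test_exact_parabola_vertex(self):
        t = np.arange(27.0, 33.25, 0.25)
        traj = make_traj(t, -((t - 30.0) ** 2))
        est = fit_peaks_parabolic(traj, window=6.0)
        assert est.peak_times.size == 1
        assert abs(est.peak_times[0] - 30.0) < 1e-9

    def test_sine_peak_to_peak_period(self):
        t = np.arange(0.0, 96.0, 0.25)
        traj = make_traj(t, np.sin(2 * np.pi * t / 24))
        est = fit_peaks_parabolic(traj, window=6.0)
        assert abs(est.period_estimate - 24.0) < 1e-6

    def test_asymmetric_waveform_peak_precedes_sinusoid_peak(self):
        # fast-rise/slow-fall waveform: the local parabola locks onto the
        # actual early maximum while the sinusoid fit averages the waveform
        truth = GroundTruth(skew=0.6)
        t = np.arange(0.0, 72.5, 0.5)
        traj = make_traj(t, np.asarray(truth.waveform(t / 24.0)))
        est = fit_peaks_parabolic(traj)
        sf = fit_sinusoid(traj, (23.0, 25.0))
        assert est.peak_times[0] < sf.peak_time_near(est.peak_times[0]) - 0.5


class TestOutlierRejection:
    def make_fit(self, err, sid="w"):
        return SinusoidFit(amplitude=1, period=24, phase=0, trend=0, baseline=0,
                           squared_error=err, n_points=100, series_id=sid)

    def test_identity_below_threshold(self):
        fits = [self.make_fit(e) for e in (0.5, 3.0, 9.9)]
        kept, n = reject_outlier_fits(fits, 10.0)
        assert kept == fits and n == 0

    def test_single_outlier(self):
        fits = [self.make_fit(e) for e in (1, 2, 3, 4, 5, 6, 7, 11)]
        kept, n = reject_outlier_fits(fits, 10.0)
        assert len(kept) == 7 and n == 1

    def test_corrupted_wells_recalled(self, kai_params, rng):
        # 96-well plate, 5 wells with gross noise: exactly those are rejected
        t = np.arange(0.0, 72.5, 0.5)
        fits = []
        bad = set(rng.choice(96, size=5, replace=False).tolist())
        for w in range(96):
            sigma = 5.0 if w in bad else 0.15
            y = np.sin(2 * np.pi * t / 24) + rng.normal(0, sigma, t.size)
            traj = normalize_trajectory(make_traj(t, y, series_id=f"w{w}"))
            fits.append(fit_sinusoid(traj, (23.0, 25.0)))
        kept, n = reject_outlier_fits(fits, 10.0)
        assert n == 5
        assert {f.series_id for f in fits} - {f.series_id for f in kept} == {
            f"w{w}" for w in bad}

    def test_all_rejected_fails(self):
        with pytest.raises(ValueError):
            reject_outlier_fits([self.make_fit(99.0)], 10.0)


class TestKendallSimilarity:
    def test_identical_and_reversed_windows(self, kai_params, rng):
        sched = DrivingSchedule(T=24.0, tau=14.0, n_cycles=2)
        t = np.arange(0.0, 3 * 24.0, 0.5)
        base = np.sin(2 * np.pi * (t % 24) / 24)
        traj = make_traj(t, base, light=np.ones_like(t, bool), schedule=sched)
        taus = kendall_entrainment_similarity(traj, sched)
        assert np.allclose(taus, 1.0)
        rev = make_traj(t, np.where(t < 48.0, base, -base))
        taus_rev = kendall_entrainment_similarity(rev, sched)
        assert np.allclose(taus_rev, -1.0)

    def test_monotone_transform_invariance(self, rng):
        sched = DrivingSchedule(T=24.0, tau=12.0, n_cycles=2)
        t = np.arange(0.0, 72.0, 0.5)
        y = rng.normal(size=t.size)
        traj = make_traj(t, y)
        ref = kendall_entrainment_similarity(traj, sched)
        transformed = make_traj(t, np.exp(3.0 * y))
        assert np.allclose(kendall_entrainment_similarity(transformed, sched), ref)

    def test_mismatched_grid_fails(self):
        sched = DrivingSchedule(T=24.0, tau=12.0, n_cycles=1)
        t = np.concatenate([np.arange(0.0, 24.0, 0.5),
                            np.arange(24.0, 48.0, 0.5) + 0.25])
        traj = make_traj(t, np.sin(t))
        with pytest.raises(ValueError, match="grids"):
            kendall_entrainment_similarity(traj, sched)

    def test_entrained_synthetic_trace(self, linear_truth, rng):
        # a stably entrained oscillator repeats its daytime waveform after
        # release, giving high rank correlation from the second cycle on
        linear_truth.noise_sigma = 0.05
        sched = DrivingSchedule(T=24.0, tau=12.0, n_cycles=5)
        traj = generate_reporter_timeseries(linear_truth, sched, rng)[0]
        taus = kendall_entrainment_similarity(traj, sched)
        assert np.all(taus[1:] > 0.8)


class TestDarkPulseShift:
    def make_fit(self, phase, period=24.0):
        return SinusoidFit(amplitude=1, period=period, phase=phase, trend=0,
                           baseline=0, squared_error=0.1, n_points=96)

    def test_perturbed_equals_control(self):
        fits = [self.make_fit(0.3) for _ in range(4)]
        m = dark_pulse_phase_shift(fits, fits, t_pulse_start=30.0, pulse_duration=12.0)
        assert m.delta_peak_time == pytest.approx(0.0, abs=1e-12)
        assert m.sd == pytest.approx(0.0)

    def test_phase_formula_identity(self):
        # phi = -pi/2, T = 24, t = 24 gives theta-hat = 1 = 0 cycles
        fits = [self.make_fit(-np.pi / 2)]
        m = dark_pulse_phase_shift(fits, fits, t_pulse_start=24.0, pulse_duration=12.0)
        assert m.phase_at_perturbation == pytest.approx(0.0, abs=1e-12)

    def test_known_shift_recovered(self):
        control = [self.make_fit(0.0) for _ in range(4)]
        shift_h = 3.5  # delay the perturbed rhythm by 3.5 h (larger phi peaks later)
        pert = [self.make_fit(2 * np.pi * shift_h / 24.0) for _ in range(4)]
        m = dark_pulse_phase_shift(pert, control, 30.0, 12.0)
        assert m.delta_peak_time == pytest.approx(shift_h, abs=1e-9)


class TestWeightedRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = regress_slope_with_errors(x, 0.5 * x + 1.0)
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_sd == pytest.approx(0.0, abs=1e-12)

    def test_equal_weights_match_ols(self, rng):
        x = np.arange(12.0)
        y = 0.7 * x + rng.normal(0, 1, x.size)
        wfit = regress_slope_with_errors(x, y, np.full(x.size, 2.0))
        ofit = regress_slope_with_errors(x, y)
        assert wfit.slope == pytest.approx(ofit.slope, abs=1e-12)
        assert wfit.intercept == pytest.approx(ofit.intercept, abs=1e-12)

    def test_degenerate_x_fails(self):
        with pytest.raises(ValueError):
            regress_slope_with_errors([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


@settings(deadline=None, max_examples=25)
@given(phi=st.floats(0.0, 2 * np.pi - 1e-9),
       amp=st.floats(0.1, 10.0),
       period=st.floats(23.1, 24.9))
def test_sinusoid_recovery_property(phi, amp, period):
    """Noiseless sinusoids are recovered to 1e-6 for any phase and amplitude."""
    t = np.arange(0.0, 72.5, 0.5)
    traj = TimeSeriesTrajectory(
        times=t, values=amp * np.sin(2 * np.pi * t / period - phi),
        light=np.ones_like(t, dtype=bool))
    f = fit_sinusoid(traj, (23.0, 25.0))
    assert abs(f.amplitude - amp) < 1e-6 * max(1.0, amp)
    assert abs(f.period - period) < 1e-6
    want = phi if phi <= np.pi else phi - 2 * np.pi
    assert abs((f.phase - want + np.pi) % (2 * np.pi) - np.pi) < 1e-6
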