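"""Step-response construction, linearization, and bootstrap propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cyanoclock._phase import wrap_cycles
from cyanoclock.rhythms import SinusoidFit
from cyanoclock.stepresponse import (
    LinearStepParams,
    StepExperimentSet,
    StepResponseFunction,
    assemble_step_response,
    bootstrap_master_dataset,
    bootstrap_slopes,
    linearize_step_response,
    measure_step_responses,
    polarization_to_phosphorylation_phase,
    step_phase_shift,
)
from cyanoclock.synth import GroundTruth, generate_step_experiment

from conftest import linear_steps


def make_fit(phase, period=24.0):
    return SinusoidFit(amplitude=1, period=period, phase=phase, trend=0,
                       baseline=0, squared_error=0.0, n_points=100)


class TestStepPhaseShift:
    def test_identical_fits_zero_shift(self):
        f = make_fit(0.7)
        for t_step in (3.0, 11.5, 26.0):
            _, dth = step_phase_shift(f, f, t_step)
            assert dth == pytest.approx(0.0, abs=1e-12)

    def test_phase_formula(self):
        theta, _ = step_phase_shift(make_fit(0.0), make_fit(0.0), 12.0)
        assert theta == pytest.approx(0.5, abs=1e-12)

    def test_constant_offset_invariance(self):
        # adding a constant to both signals only changes baselines, which the
        # phase formula never touches
        a, b = make_fit(0.4), make_fit(1.1)
        a2 = SinusoidFit(**{**a.__dict__, "baseline": 57.0})
        b2 = SinusoidFit(**{**b.__dict__, "baseline": 57.0})
        assert step_phase_shift(a, b, 9.0) == step_phase_shift(a2, b2, 9.0)

    def test_disentangles_shift_from_period_change(self):
        # a reaction stepped at t=12 with an instantaneous -0.1 cycle shift
        # and a period change 24 -> 25.7: its post-step apparent phase at the
        # step time differs from the control phase by exactly the shift
        t_step, shift = 12.0, -0.1
        control = make_fit(0.0, period=24.0)
        theta_step = t_step / 24.0
        # post-step phase evolves as theta_step + shift + (t - t_step)/25.7;
        # as a sinusoid in t: phase angle phi = 2*pi*(t_step/25.7 - theta_step - shift)
        phi_pert = 2 * np.pi * (t_step / 25.7 - theta_step - shift)
        pert = make_fit(phi_pert, period=25.7)
        theta, dth = step_phase_shift(control, pert, t_step,
                                      T_control=24.0, T_perturbed=25.7)
        assert theta == pytest.approx(0.5, abs=1e-12)
        assert dth == pytest.approx(shift, abs=1e-12)


class TestAssemble:
    def test_two_zero_nodes_give_zero_function(self):
        F = assemble_step_response([(0.0, 0.0), (0.5, 0.0)], kind="dawn")
        assert np.allclose(F(np.linspace(0, 1, 50)), 0.0)

    def test_midpoint_interpolation(self):
        F = assemble_step_response([(0.2, 0.1), (0.6, -0.3)], kind="dusk")
        assert F(0.4) == pytest.approx(-0.1)

    def test_wraparound_matches_unrolled_interpolation(self):
        nodes = [(0.9, 0.2), (0.1, -0.1), (0.4, 0.05)]
        F = assemble_step_response(nodes, kind="dawn")
        # oracle: interpolate on three explicit unrolled periods
        ph = np.array([0.1, 0.4, 0.9])
        sh = np.array([-0.1, 0.05, 0.2])
        xp = np.concatenate([ph - 1, ph, ph + 1])
        fp = np.concatenate([sh, sh, sh])
        grid = np.linspace(0, 1, 201, endpoint=False)
        assert np.allclose(F(grid), np.interp(grid, xp, fp), atol=1e-12)

    def test_conflicting_duplicates_fail(self):
        with pytest.raises(ValueError, match="conflicting"):
            assemble_step_response([(0.3, 0.1), (0.3, -0.1), (0.7, 0.0)], "dawn")

    def test_periodicity_exact(self):
        F = assemble_step_response([(0.15, 0.1), (0.5, -0.2), (0.8, 0.02)], "dusk")
        grid = np.linspace(0, 1, 97, endpoint=False)
        # one float rounding from wrapping the argument is the only slack
        assert np.allclose(F(grid), F(grid + 1.0), atol=1e-12, rtol=0)
        assert np.allclose(F(grid), F(grid - 3.0), atol=1e-12, rtol=0)


class TestLinearize:
    def test_exact_linear_region(self):
        # nodes on a -0.4-slope line through CT 14 (dusk anchor)
        th = np.linspace(6 / 24, 22 / 24, 9)
        F = StepResponseFunction(kind="dusk", phases=th,
                                 shifts=-0.4 * (th - 14 / 24))
        lin = linearize_step_response(F, (6.0, 22.0))
        assert lin.slope == pytest.approx(0.4, abs=1e-12)
        assert lin.anchor == pytest.approx(14 / 24, abs=1e-9)

    def test_breakpointed_function_is_periodic_and_winding_zero(self):
        lin = LinearStepParams(kind="dawn", slope=0.34, anchor=1 / 12,
                               breakpoint=1 / 12 + 0.5)
        grid = np.linspace(0, 1, 10000, endpoint=False)
        vals = lin(grid)
        assert np.allclose(lin(grid + 1.0), vals, atol=1e-12)
        assert np.max(np.abs(vals)) < 1.0
        # single jump of one slope-cycle at the breakpoint
        jumps = np.abs(np.diff(vals))
        assert (jumps > 0.01).sum() == 1

    def test_wrap_range_selection(self):
        # the dawn window (CT 18-34) wraps through 24; nodes on both sides
        th = wrap_cycles(np.linspace(18 / 24, 34 / 24, 9))
        order = np.argsort(th)
        shifts = -0.25 * (np.linspace(18 / 24, 34 / 24, 9) - 26 / 24)
        F = StepResponseFunction(kind="dawn", phases=th[order], shifts=shifts[order])
        lin = linearize_step_response(F, (18.0, 34.0))
        assert lin.slope == pytest.approx(0.25, abs=1e-9)

    def test_too_few_nodes_fail(self):
        F = assemble_step_response([(0.1, 0.0), (0.3, 0.01), (0.9, 0.0)], "dusk")
        with pytest.raises(ValueError, match="nodes"):
            linearize_step_response(F, (12.0, 16.0))


class TestBootstrapSlopes:
    def test_exact_linear_nodes_all_equal(self, rng):
        th = np.linspace(0.3, 0.9, 7)
        slopes = bootstrap_slopes(th, -0.4 * (th - 0.5), n_samples=50, rng=rng)
        assert np.allclose(slopes, 0.4, atol=1e-9)

    def test_bootstrap_sd_matches_analytic(self, rng):
        # Gaussian jitter of known sigma: bootstrap slope SD vs the analytic
        # OLS slope SD agree within 20 percent
        th = np.linspace(0.25, 0.92, 12)
        sigma = 0.03
        sh = -0.4 * (th - 0.5) + rng.normal(0, sigma, th.size)
        slopes = bootstrap_slopes(th, sh, n_samples=600, rng=rng)
        resid = sh - np.poly1d(np.polyfit(th, sh, 1))(th)
        s2 = resid @ resid / (th.size - 2)
        analytic_sd = np.sqrt(s2 / ((th - th.mean()) @ (th - th.mean())))
        assert abs(slopes.std(ddof=1) - analytic_sd) < 0.2 * analytic_sd

    def test_too_few_unique_points(self, rng):
        with pytest.raises(ValueError):
            bootstrap_slopes([0.5, 0.5], [0.1, 0.1], rng=rng)


class TestPolarizationConversion:
    def test_known_values_and_inverse(self):
        assert polarization_to_phosphorylation_phase(1 / 3) == pytest.approx(0.0)
        assert polarization_to_phosphorylation_phase(0.0) == pytest.approx(2 / 3)
        th = np.linspace(0, 1, 13, endpoint=False)
        back = wrap_cycles(polarization_to_phosphorylation_phase(th) + 1 / 3)
        assert np.allclose(back, th, atol=1e-12)


def build_master(truth, rng, step_times=None):
    step_times = np.arange(2.0, 26.0, 2.0) if step_times is None else step_times
    up = generate_step_experiment(truth, step_times, "up", rng)
    down = generate_step_experiment(truth, step_times + 1.0, "down", rng)
    members = up.members + [m for m in down.members if m.role == "stepped"]
    return StepExperimentSet(members=members)


class TestRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_linear_truth_recovered(self, kai_params, rng, seed):
        gen = np.random.default_rng(seed)
        l_true, d_true = gen.uniform(0.2, 0.6, size=2)
        L, D = linear_steps(l=l_true, d=d_true)
        truth = GroundTruth(params=kai_params, L=L, D=D, noise_sigma=0.15,
                            cadence=0.25)
        meas = measure_step_responses(build_master(truth, gen))
        assert abs(meas.L_lin.slope - l_true) < 0.05
        assert abs(meas.D_lin.slope - d_true) < 0.05
        assert abs(meas.freq_ratio - kai_params.freq_ratio) < 0.02

    def test_zero_shift_truth_gives_zero_functions(self, kai_params):
        truth = GroundTruth(params=kai_params, L=None, D=None, noise_sigma=0.05,
                            cadence=0.25)
        meas = measure_step_responses(build_master(truth, np.random.default_rng(7)))
        assert np.max(np.abs(meas.L.shifts)) < 0.03
        assert np.max(np.abs(meas.D.shifts)) < 0.03

    def test_out_of_phase_replicate_sets(self, linear_truth):
        # two tubes thawed 12 h apart: generators support arbitrary theta0
        rng = np.random.default_rng(3)
        a = generate_step_experiment(linear_truth, [4.0, 8.0, 12.0], "up", rng,
                                     theta0=0.0)
        b = generate_step_experiment(linear_truth, [4.0, 8.0, 12.0], "up", rng,
                                     theta0=0.5)
        phases_a = [linear_truth.params.omega_D * m.step_time
                    for m in a.members if m.role == "stepped"]
        phases_b = [0.5 + linear_truth.params.omega_D * m.step_time
                    for m in b.members if m.role == "stepped"]
        assert not np.allclose(wrap_cycles(np.array(phases_a)),
                               wrap_cycles(np.array(phases_b)))


class TestBootstrapMaster:
    def test_seeded_single_member_reproducible(self, linear_truth):
        master = build_master(linear_truth, np.random.default_rng(11))
        e1 = bootstrap_master_dataset(master, n=1, seed=42)
        e2 = bootstrap_master_dataset(master, n=1, seed=42)
        m1, m2 = e1.members[0], e2.members[0]
        assert m1.T_day == m2.T_day and m1.T_night == m2.T_night
        assert np.array_equal(m1.L.shifts, m2.L.shifts)

    def test_zero_noise_members_match_point_estimate(self, kai_params):
        L, D = linear_steps(l=0.4, d=0.4)
        truth = GroundTruth(params=kai_params, L=L, D=D, noise_sigma=0.0,
                            cadence=0.5)
        master = build_master(truth, np.random.default_rng(0))
        point = measure_step_responses(master)
        ens = bootstrap_master_dataset(master, n=5, seed=1)
        for m in ens.members:
            # identical trajectories: resampling cannot change any estimate
            assert m.T_day == pytest.approx(point.T_day, abs=1e-6)
            assert np.allclose(m.L.shifts, point.L(m.L.phases), atol=1e-5)
            assert np.allclose(m.D.shifts, point.D(m.D.phases), atol=1e-5)

    def test_ensemble_brackets_truth(self, kai_params):
        L, D = linear_steps(l=0.4, d=0.35)
        truth = GroundTruth(params=kai_params, L=L, D=D, noise_sigma=0.1,
                            cadence=0.5)
        master = build_master(truth, np.random.default_rng(5))
        ens = bootstrap_master_dataset(master, n=60, seed=2)
        grid = np.linspace(0.05, 0.95, 19)
        vals = ens.evaluate("dusk", grid)
        mean, sd = vals.mean(axis=0), vals.std(axis=0, ddof=1)
        truth_vals = np.asarray(D(grid))
        covered = np.abs(truth_vals - mean) <= 2.0 * np.maximum(sd, 1e-4)
        assert covered.mean() >= 0.9


@settings(deadline=None, max_examples=20)
@given(st.lists(st.tuples(st.floats(0, 0.999), st.floats(-0.45, 0.45)),
                min_size=3, max_size=12,
                unique_by=lambda p: round(p[0], 3)))
def test_assembled_function_properties(pairs):
    """Any assembled function is exactly 1-periodic, below one cycle in
    magnitude, and reproduces its nodes."""
    F = assemble_step_response(pairs, kind="dawn")
    grid = np.linspace(0, 1, 101, endpoint=False)
    assert np.allclose(F(grid), F(grid + 1.0), atol=1e-12, rtol=0)
    assert np.max(np.abs(F(grid))) < 1.0
    assert np.allclose(F(F.phases), F.shifts, atol=1e-12)
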