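"""Limit-cycle geometry: radial jumps, derived step responses, dynamics."""

import numpy as np
import pytest

from cyanoclock._phase import TWO_PI, wrap_pi
from cyanoclock.geometry import (
    Orbit,
    OrbitGeometry,
    PlanarState,
    integrate_relaxation,
    peak_time_dynamic,
    radial_jump,
    simulate_entrainment_dynamic,
    simulate_entrainment_instant,
    slope_over_grid,
    step_response_from_geometry,
)


def brute_force_nearest(theta_source, source, target, n=10000):
    p = source.point(theta_source)
    cand = np.arange(n) / n * TWO_PI
    pts = np.stack([target.center[0] + target.r_of_theta(cand) * np.cos(cand),
                    target.center[1] + target.r_of_theta(cand) * np.sin(cand)])
    d2 = (pts[0] - p[0]) ** 2 + (pts[1] - p[1]) ** 2
    return cand[int(np.argmin(d2))]


class TestRadialJump:
    def test_concentric_preserves_angle(self):
        a, b = Orbit((0, 0), 1.0), Orbit((0, 0), 3.0)
        th = np.linspace(0, TWO_PI, 17)
        assert np.allclose(wrap_pi(radial_jump(th, a, b) - th), 0.0, atol=1e-12)

    def test_round_trip_identity_when_concentric(self):
        a, b = Orbit((0, 0), 1.0), Orbit((0, 0), 2.5)
        th = 1.234
        back = radial_jump(radial_jump(th, a, b), b, a)
        assert wrap_pi(back - th) == pytest.approx(0.0, abs=1e-12)

    def test_r2_x2_characteristic_points(self):
        day, night = Orbit((0, 0), 1.0), Orbit((0, 2.0), 2.0)
        # the bottom of the day orbit lies on the ray straight down from the
        # night center: zero shift
        shift_bottom = wrap_pi(radial_jump(-np.pi / 2, day, night) - (-np.pi / 2))
        assert shift_bottom == pytest.approx(0.0, abs=1e-12)
        # the top of the day orbit (0, 1) is seen from the night center (0, 2)
        # straight down: it maps to the night phase -pi/2, half a cycle away
        top = radial_jump(np.pi / 2, day, night)
        assert wrap_pi(top - (-np.pi / 2)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_nearest_point(self):
        gen = np.random.default_rng(2)
        for _ in range(100):
            source = Orbit((0, 0), 1.0)
            target = Orbit((0, float(gen.uniform(0, 4))), float(gen.uniform(0.2, 4)))
            th = float(gen.uniform(0, TWO_PI))
            p = source.point(th)
            if np.hypot(p[0] - target.center[0], p[1] - target.center[1]) < 1e-6:
                continue
            got = radial_jump(th, source, target)
            want = brute_force_nearest(th, source, target)
            assert abs(wrap_pi(got - want)) < TWO_PI / 10000 + 1e-9

    def test_degenerate_center_fails(self):
        day, night = Orbit((0, 0), 1.0), Orbit((0, 1.0), 2.0)
        with pytest.raises(ValueError, match="undefined"):
            radial_jump(np.pi / 2, day, night)

    def test_rotation_equivariance(self):
        # rotating the whole geometry rotates all jump angles identically
        gen = np.random.default_rng(5)
        for _ in range(20):
            X, R = gen.uniform(0.5, 3, 2)
            alpha = float(gen.uniform(0, TWO_PI))
            th = float(gen.uniform(0, TWO_PI))
            plain = radial_jump(th, Orbit((0, 0), 1.0), Orbit((0, X), R))
            ca, sa = np.cos(alpha), np.sin(alpha)
            rot_center = (-X * sa, X * ca)
            rotated = radial_jump(th + alpha, Orbit((0, 0), 1.0),
                                  Orbit(rot_center, R))
            assert abs(wrap_pi(rotated - plain - alpha)) < 1e-9


class TestDerivedStepFunctions:
    def test_concentric_gives_zero_functions(self):
        L, D = step_response_from_geometry(OrbitGeometry(R=2.0, X=1e-9))
        assert np.max(np.abs(L.shifts)) < 1e-6
        assert np.max(np.abs(D.shifts)) < 1e-6

    def test_central_regions_nearly_linear(self):
        # for R = X = 2 both derived functions have a broad near-linear
        # region (L is exactly linear with slope -1/2 over the mid-cycle;
        # D is near-linear around its zero)
        L, D = step_response_from_geometry(OrbitGeometry(R=2.0, X=2.0), n_grid=360)
        slopes = {}
        for F, center in ((D, 0.0), (L, 0.5)):
            # quarter cycle around the center of the linear region
            sel = np.abs((F.phases - center + 0.5) % 1 - 0.5) < 0.125
            x = ((F.phases[sel] - center + 0.5) % 1) - 0.5
            y = F.shifts[sel]
            s, c = np.polyfit(x, y, 1)
            pred = s * x + c
            r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
            assert r2 > 0.99
            slopes[F.kind] = -s
        # the positive-convention slopes predict the simulated tracking
        # coefficient via the closed-form m(l, d)
        from cyanoclock.lineartheory import slope_m
        l, d = slopes["dawn"], slopes["dusk"]
        assert slope_m(l, d, 1.0) == pytest.approx(0.40, abs=0.02)

    def test_winding_number_preserved(self):
        # the jump map theta -> theta + F(theta) winds once per cycle:
        # total increment of (phase + shift) over a full cycle is one cycle
        L, D = step_response_from_geometry(OrbitGeometry(R=2.0, X=1.5), n_grid=720)
        for F in (L, D):
            image = F.phases + F.shifts
            incr = np.diff(np.concatenate([image, [image[0] + 1.0]]))
            assert np.sum(incr) == pytest.approx(1.0, abs=1e-9)
            assert np.max(np.abs(F.shifts)) < 1.0


class TestInstantEntrainment:
    def test_concentric_never_entrains(self):
        geom = OrbitGeometry(R=2.0, X=0.0)
        for tau in (6.0, 12.0, 18.0):
            _, ok = simulate_entrainment_instant(geom, tau)
            assert not ok

    def test_r2_x2_entrains_linearly(self):
        geom = OrbitGeometry(R=2.0, X=2.0)
        taus = np.arange(6.0, 18.1, 1.0)
        phases = []
        for tau in taus:
            ph, ok = simulate_entrainment_instant(geom, float(tau))
            assert ok
            phases.append(ph)
        tpk = np.unwrap(np.mod(np.pi / 2 - np.unwrap(phases), TWO_PI)) / geom.omega
        s, c = np.polyfit(taus, tpk, 1)
        resid = tpk - (s * taus + c)
        assert np.mean(np.abs(resid)) < 0.1 * np.ptp(tpk)

    def test_huge_night_orbit_tracks_dusk(self):
        # night cycle much larger than the day cycle: dusk is strongly
        # resetting, dawn barely matters (l ~ 0, d ~ 1)
        geom = OrbitGeometry(R=50.0, X=2.0)
        taus = np.arange(6.0, 18.1, 2.0)
        phases = [simulate_entrainment_instant(geom, float(t))[0] for t in taus]
        tpk = np.unwrap(np.mod(np.pi / 2 - np.unwrap(phases), TWO_PI)) / geom.omega
        assert np.polyfit(taus, tpk, 1)[0] == pytest.approx(1.0, abs=0.1)


class TestDynamics:
    def test_on_orbit_circular_start_stays(self):
        geom = OrbitGeometry(R=2.0, X=2.0, a=1.0)
        orbit = geom.day_orbit
        _, ths, rs = integrate_relaxation(PlanarState(0.3, 1.0), geom, orbit,
                                          24.0, dt=0.01)
        assert np.max(np.abs(rs - 1.0)) < 1e-10

    def test_on_orbit_elliptical_start_stays(self):
        geom = OrbitGeometry(R=2.0, X=2.0, a=1.0, rho_day=1.5)
        orbit = geom.day_orbit
        state = PlanarState(0.3, float(orbit.r_of_theta(0.3)))
        _, ths, rs = integrate_relaxation(state, geom, orbit, 12.0, dt=0.02)
        assert np.max(np.abs(rs - orbit.r_of_theta(ths))) < 5e-4

    def test_radial_decay_matches_closed_form(self):
        geom = OrbitGeometry(R=2.0, X=2.0, a=0.7)
        orbit = geom.day_orbit
        times, _, rs = integrate_relaxation(PlanarState(0.0, 3.0), geom, orbit,
                                            12.0, dt=0.01)
        expect = 1.0 + 2.0 * np.exp(-0.7 * times)
        assert np.max(np.abs(rs - expect)) < 1e-4

    def test_velocity_modulation_completes_one_cycle_per_period(self):
        geom = OrbitGeometry(R=2.0, X=2.0, a=1.0, eps_ratio=0.5)
        _, ths, _ = integrate_relaxation(PlanarState(0.1, 1.0), geom,
                                         geom.day_orbit, 24.0, dt=0.01)
        assert ths[-1] - ths[0] == pytest.approx(TWO_PI, abs=1e-6)

    def test_convergence_under_dt_refinement(self):
        geom = OrbitGeometry(R=2.0, X=2.0, a=1.0, rho_day=1.3)
        orbit = geom.day_orbit
        state = PlanarState(0.5, 2.0)
        finals = []
        for dt in (0.04, 0.02):
            _, ths, rs = integrate_relaxation(state, geom, orbit, 8.0, dt=dt)
            finals.append((ths[-1], rs[-1]))
        assert abs(finals[0][0] - finals[1][0]) < 1e-4
        assert abs(finals[0][1] - finals[1][1]) < 1e-4

    def test_trajectories_stay_bounded(self):
        geom = OrbitGeometry(R=3.0, X=2.0, a=0.5, eps_ratio=0.4)
        _, _, rs = integrate_relaxation(PlanarState(0.0, 6.0), geom,
                                        geom.night_orbit, 48.0, dt=0.02)
        assert np.max(rs) <= 6.0 + 1e-9


class TestPeakTime:
    def test_quarter_cycle_from_phase_zero(self):
        orbit = Orbit((0, 0), 1.0)
        t = np.arange(0, 12.01, 0.01)
        th = 0.0 + TWO_PI / 24 * t
        tpk = peak_time_dynamic(t, th, np.ones_like(t), orbit)
        assert tpk == pytest.approx(6.0, abs=1e-9)

    def test_zero_when_starting_at_peak_phase(self):
        orbit = Orbit((0, 0), 1.0)
        t = np.arange(0, 12.01, 0.01)
        th = np.pi / 2 + TWO_PI / 24 * t
        assert peak_time_dynamic(t, th, np.ones_like(t), orbit) == pytest.approx(
            0.0, abs=1e-9)

    def test_relaxation_crossing_matches_finer_grid(self):
        geom = OrbitGeometry(R=2.0, X=2.0, a=1.0)
        orbit = geom.day_orbit
        state = PlanarState(0.0, 3.0)
        vals = []
        for dt in (0.01, 0.001):
            t, th, r = integrate_relaxation(state, geom, orbit, 24.0, dt=dt)
            vals.append(peak_time_dynamic(t, th, r, orbit))
        assert abs(vals[0] - vals[1]) < 1e-3

    def test_never_relaxing_fails(self):
        orbit = Orbit((0, 0), 1.0)
        t = np.arange(0, 5.01, 0.01)
        with pytest.raises(ValueError, match="relax"):
            peak_time_dynamic(t, t * 0.1, np.full_like(t, 9.0), orbit)


class TestVariants:
    def test_instant_limit_matches_strong_attraction(self):
        # a = 10 (half-time 4 min) is operationally the instant-jump limit
        geom_i = OrbitGeometry(R=2.0, X=2.0)
        geom_a = OrbitGeometry(R=2.0, X=2.0, a=10.0)
        taus = np.arange(6.0, 18.1, 2.0)
        ph = [simulate_entrainment_instant(geom_i, float(t))[0] for t in taus]
        tpk_i = np.unwrap(np.mod(np.pi / 2 - np.unwrap(ph), TWO_PI)) / geom_i.omega
        tpk_a = [simulate_entrainment_dynamic(geom_a, float(t))[0] for t in taus]
        m_i = np.polyfit(taus, tpk_i, 1)[0]
        m_a = np.polyfit(taus, np.unwrap(tpk_a, period=24.0), 1)[0]
        assert abs(m_i - m_a) < 0.05

    def test_concentric_masked_over_grid(self):
        out = slope_over_grid(np.array([0.5, 2.0]), np.array([0.0]),
                              taus=np.arange(6.0, 18.1, 3.0))
        assert out["mask"].all()

    def test_modulation_reference_option(self):
        geom_d = OrbitGeometry(R=2.0, X=2.0, a=1.0, eps_ratio=0.3,
                               modulation_reference="dawn")
        geom_a = OrbitGeometry(R=2.0, X=2.0, a=1.0, eps_ratio=0.3,
                               modulation_reference="absolute")
        t_d, ok_d = simulate_entrainment_dynamic(geom_d, 10.0)
        t_a, ok_a = simulate_entrainment_dynamic(geom_a, 10.0)
        assert ok_d and ok_a  # both defined; values may differ
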