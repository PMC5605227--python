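"""Day/night limit-cycle geometry and the entrainment it produces.

The clock cycle in daytime conditions is a planar limit cycle (unit circle
at the origin); darkness deforms it into a night orbit of radius R centered
at (0, X).  In the strongly attracting limit, dusk and dawn transitions are
instantaneous radial jumps toward the center of the newly active orbit, so
the step-response functions L(theta) and D(theta) are determined purely by
the relative geometry (R, X).  Relaxed-assumption variants treat the orbit
attraction explicitly (finite rate a, with half-time ln 2 / a), allow
elliptical orbits (major/minor ratios rho, major axes along y), and allow
sinusoidally modulated angular velocity.

Angles here are radians; the oscillator peak is at theta = pi/2 on the day
orbit.  Conversion to the cycles convention of :mod:`cyanoclock.phasemodel`
(phase 0.5 at the peak) maps theta -> (theta/(2*pi) + 1/4) mod 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from ._phase import TWO_PI, wrap_cycles, wrap_pi
from .stepresponse import StepResponseFunction

__all__ = [
    "Orbit",
    "OrbitGeometry",
    "PlanarState",
    "radial_jump",
    "rad_to_cycles",
    "step_response_from_geometry",
    "simulate_entrainment_instant",
    "simulate_entrainment_dynamic",
    "slope_over_grid",
    "integrate_relaxation",
    "peak_time_dynamic",
]

OMEGA_DEFAULT = TWO_PI / 24.0  # rad/h


def rad_to_cycles(theta):
    """Day-orbit angle (radians, peak at pi/2) to clock phase in cycles
    (peak at 0.5)."""
    return wrap_cycles(np.asarray(theta, dtype=float) / TWO_PI + 0.25)


@dataclass
class Orbit:
    """A circular or elliptical limit cycle.

    ``radius`` is the minor-axis radius (along x); the major axis (along y)
    has length ``rho * radius``.  ``rho = 1`` gives a circle.
    """

    center: tuple[float, float]
    radius: float
    rho: float = 1.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("orbit radius must be positive")
        if self.rho < 1.0:
            raise ValueError("major/minor ratio rho must be >= 1")

    @property
    def is_circle(self) -> bool:
        return self.rho == 1.0

    def r_of_theta(self, theta):
        """Polar radius of the orbit at angle theta about its center."""
        theta = np.asarray(theta, dtype=float)
        inv2 = (np.cos(theta) ** 2 / self.radius**2
                + np.sin(theta) ** 2 / (self.rho * self.radius) ** 2)
        out = inv2 ** -0.5
        return out if out.ndim else float(out)

    def rdot_of_theta(self, theta, theta_dot):
        """Radial velocity of a point tracking the orbit at angular rate
        theta_dot."""
        theta = np.asarray(theta, dtype=float)
        R2 = self.radius**2
        rho2R2 = (self.rho * self.radius) ** 2
        inv2 = np.cos(theta) ** 2 / R2 + np.sin(theta) ** 2 / rho2R2
        out = (-0.5 * inv2 ** -1.5
               * (-2.0 * theta_dot * np.cos(theta) * np.sin(theta) / R2
                  + 2.0 * theta_dot * np.cos(theta) * np.sin(theta) / rho2R2))
        return out if out.ndim else float(out)

    def point(self, theta) -> np.ndarray:
        r = self.r_of_theta(theta)
        return np.array([self.center[0] + r * np.cos(theta),
                         self.center[1] + r * np.sin(theta)])

    def signed_distance(self, r: float, theta: float) -> float:
        """Signed distance from polar point (r, theta) to the orbit
        (positive outside).  For ellipses the nearest point is found by
        bounded 1-D minimization over the parameter angle within
        theta +/- pi/2."""
        if self.is_circle:
            return r - self.radius
        p = np.array([r * np.cos(theta), r * np.sin(theta)])

        def dist2(psi):
            e = np.array([self.radius * np.cos(psi),
                          self.rho * self.radius * np.sin(psi)])
            return float((p - e) @ (p - e))

        res = optimize.minimize_scalar(
            dist2, bounds=(theta - np.pi / 2, theta + np.pi / 2),
            method="bounded", options={"xatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(
                f"ellipse nearest-point search failed at (r={r:.4f}, theta={theta:.4f})"
            )
        d = float(np.sqrt(res.fun))
        return d if r >= self.r_of_theta(theta) else -d


@dataclass
class OrbitGeometry:
    """Relative geometry of the day and night limit cycles plus dynamics.

    The day orbit has unit (minor) radius at the origin; the night orbit has
    (minor) radius ``R`` and is centered at (0, ``X``).  ``a`` is the orbit
    attraction rate in 1/h (``None`` selects the instantaneous-jump limit);
    ``eps_ratio`` = epsilon/omega is the fractional angular-velocity
    modulation; ``modulation_reference`` fixes whether the modulation clock
    sin(omega*t) restarts at each dawn (default) or runs on absolute time.
    """

    R: float = 2.0
    X: float = 2.0
    a: Optional[float] = None
    rho_day: float = 1.0
    rho_night: float = 1.0
    eps_ratio: float = 0.0
    omega: float = OMEGA_DEFAULT
    modulation_reference: str = "dawn"

    def __post_init__(self):
        if self.R <= 0 or self.X < 0:
            raise ValueError("need R > 0 and X >= 0")
        if self.a is not None and self.a <= 0:
            raise ValueError("attraction rate a must be positive")
        if self.modulation_reference not in ("dawn", "absolute"):
            raise ValueError("modulation_reference must be 'dawn' or 'absolute'")
        if abs(self.eps_ratio) >= 1.0:
            raise ValueError("|eps_ratio| must stay below 1 (theta-dot > 0)")

    @property
    def day_orbit(self) -> Orbit:
        return Orbit(center=(0.0, 0.0), radius=1.0, rho=self.rho_day)

    @property
    def night_orbit(self) -> Orbit:
        return Orbit(center=(0.0, self.X), radius=self.R, rho=self.rho_night)

    @property
    def half_time(self) -> Optional[float]:
        """Relaxation half-time ln(2)/a in hours (None in the instant limit)."""
        return None if self.a is None else float(np.log(2.0) / self.a)


@dataclass
class PlanarState:
    """Oscillator state in polar coordinates relative to the active orbit."""

    theta: float  # radians, unwrapped
    r: float

    def to_xy(self, orbit: Orbit) -> np.ndarray:
        return np.array([orbit.center[0] + self.r * np.cos(self.theta),
                         orbit.center[1] + self.r * np.sin(self.theta)])

    @classmethod
    def from_xy(cls, xy, orbit: Orbit) -> "PlanarState":
        dx = xy[0] - orbit.center[0]
        dy = xy[1] - orbit.center[1]
        return cls(theta=float(np.arctan2(dy, dx)), r=float(np.hypot(dx, dy)))


def radial_jump(theta_source, source_orbit: Orbit, target_orbit: Orbit):
    """Angle on the target orbit reached by an instantaneous radial jump.

    The oscillator at ``theta_source`` on the source orbit jumps to the
    nearest point of the target orbit, i.e. along the ray from the target
    center through the source point.  Undefined (raises) when the source
    point coincides with the target center.  Broadcasts over angle arrays.
    """
    theta_source = np.asarray(theta_source, dtype=float)
    r = source_orbit.r_of_theta(theta_source)
    px = source_orbit.center[0] + r * np.cos(theta_source) - target_orbit.center[0]
    py = source_orbit.center[1] + r * np.sin(theta_source) - target_orbit.center[1]
    if np.any(np.hypot(px, py) < 1e-12):
        raise ValueError("source point coincides with the target orbit center; "
                         "jump direction undefined")
    out = np.arctan2(py, px)
    return out if out.ndim else float(out)


def step_response_from_geometry(
    geom: OrbitGeometry, n_grid: int = 240
) -> tuple[StepResponseFunction, StepResponseFunction]:
    """Tabulate L and D produced by radial jumps between the two orbits.

    D maps day-orbit phases through the dusk (day-to-night) jump; L maps
    night-orbit phases through the dawn jump.  Shifts are wrapped to half a
    cycle (winding 0) and the node phases converted to the cycles convention
    of the phase model.
    """
    day, night = geom.day_orbit, geom.night_orbit
    th = np.arange(n_grid) / n_grid * TWO_PI

    def build(kind, source, target):
        r = source.r_of_theta(th)
        px = source.center[0] + r * np.cos(th) - target.center[0]
        py = source.center[1] + r * np.sin(th) - target.center[1]
        valid = np.hypot(px, py) > 1e-9  # drop nodes at the target center
        shift_rad = wrap_pi(np.arctan2(py[valid], px[valid]) - th[valid])
        phases = rad_to_cycles(th[valid])
        order = np.argsort(phases)
        return StepResponseFunction(kind=kind, phases=phases[order],
                                    shifts=shift_rad[order] / TWO_PI)

    D = build("dusk", day, night)
    L = build("dawn", night, day)
    return L, D


# ---------------------------------------------------------------------------
# instantaneous-jump entrainment


def simulate_entrainment_instant(
    geom: OrbitGeometry,
    tau: float,
    T: float = 24.0,
    n_cycles: int = 30,
    theta0s: Sequence[float] = (np.pi / 4, 5 * np.pi / 4),
    tol: float = np.pi / 180.0,
):
    """Entrained dawn phase for one day length in the instant-jump model.

    Each initial phase is iterated through ``n_cycles`` light-dark cycles
    (day advance, dusk jump, night advance, dawn jump).  The run fails the
    entrainment criteria if the dawn phases after the last two cycles differ
    by more than ``tol`` radians, or the runs started from different initial
    phases end more than ``tol`` apart.

    Returns ``(phase, ok)``: the dawn phase (radians, wrapped) after the
    final cycle and a validity flag.
    """
    day, night = geom.day_orbit, geom.night_orbit
    finals, penult = [], []
    for th0 in theta0s:
        th = float(th0)
        prev = None
        try:
            for n in range(n_cycles):
                th = th + geom.omega * tau
                th = float(radial_jump(th, day, night))
                th = th + geom.omega * (T - tau)
                th = float(radial_jump(th, night, day))
                if n == n_cycles - 2:
                    prev = th
        except ValueError:
            # trajectory hit the opposite orbit's center: jump undefined,
            # phase information destroyed -> treat as failed entrainment
            return float("nan"), False
        finals.append(th)
        penult.append(prev)
    ok = all(abs(wrap_pi(f - p)) <= tol for f, p in zip(finals, penult))
    ok = ok and all(
        abs(wrap_pi(f - finals[0])) <= tol for f in finals[1:]
    )
    return float(np.mod(finals[0], TWO_PI)), bool(ok)


# ---------------------------------------------------------------------------
# dynamical variants


def _theta_advance(theta0, duration, geom: OrbitGeometry, t_mod0: float):
    """Closed-form angular advance with optional sinusoidal modulation."""
    if geom.eps_ratio == 0.0:
        return theta0 + geom.omega * duration
    w = geom.omega
    return (theta0 + w * duration
            + geom.eps_ratio * (np.cos(w * t_mod0) - np.cos(w * (t_mod0 + duration))))


def _advance_circular_segment(state: PlanarState, orbit: Orbit, duration: float,
                              geom: OrbitGeometry, t_mod0: float) -> PlanarState:
    """Exact propagation over one light or dark segment on a circular orbit."""
    theta = _theta_advance(state.theta, duration, geom, t_mod0)
    r = orbit.radius + (state.r - orbit.radius) * np.exp(-geom.a * duration)
    return PlanarState(theta=float(theta), r=float(r))


def integrate_relaxation(
    state: PlanarState,
    geom: OrbitGeometry,
    orbit: Orbit,
    duration: float,
    dt: float = 0.01,
    t_mod0: float = 0.0,
):
    """Fixed-step RK4 integration of the relaxation dynamics on one orbit.

    Integrates ``theta' = omega*(1 + eps_ratio*sin(omega*t))`` and the radial
    attraction law (exponential pull toward the circle, or toward the
    nearest point of the ellipse with the tracking term r'_ellipse) for
    ``duration`` hours.  Returns (times, thetas, radii) arrays including
    both endpoints.  Orbit switching is the caller's responsibility.
    """
    if geom.a is None:
        raise ValueError("dynamical integration requires a finite attraction rate a")
    n = int(round(duration / dt))
    if abs(n * dt - duration) > 1e-9:
        raise ValueError(f"duration={duration} is not a multiple of dt={dt}")

    def rhs(t_mod, th, r):
        th_dot = geom.omega * (1.0 + geom.eps_ratio * np.sin(geom.omega * t_mod))
        if orbit.is_circle:
            r_dot = -geom.a * (r - orbit.radius)
        else:
            r_dot = (-geom.a * orbit.signed_distance(r, th)
                     + orbit.rdot_of_theta(th, th_dot))
        return th_dot, r_dot

    times = np.arange(n + 1) * dt
    thetas = np.empty(n + 1)
    radii = np.empty(n + 1)
    th, r = state.theta, state.r
    thetas[0], radii[0] = th, r
    for i in range(n):
        t0 = t_mod0 + times[i]
        k1 = rhs(t0, th, r)
        k2 = rhs(t0 + dt / 2, th + dt / 2 * k1[0], r + dt / 2 * k1[1])
        k3 = rhs(t0 + dt / 2, th + dt / 2 * k2[0], r + dt / 2 * k2[1])
        k4 = rhs(t0 + dt, th + dt * k3[0], r + dt * k3[1])
        th += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        r += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        thetas[i + 1], radii[i + 1] = th, r
    return times, thetas, radii


def peak_time_dynamic(
    times, thetas, radii, orbit: Orbit, rel_tol: float = 0.01
):
    """Time to reach phase pi/2 after relaxing back onto the (day) orbit.

    Scans a sampled trajectory (as returned by :func:`integrate_relaxation`
    starting at the final dawn) for the first index where the radius is
    within ``rel_tol`` (fractionally) of the orbit radius at the current
    angle, then returns the linearly interpolated time of the first
    subsequent crossing of theta = pi/2 (mod 2*pi).  Raises if the
    oscillator never relaxes or never crosses within the trajectory.
    """
    times = np.asarray(times, float)
    thetas = np.asarray(thetas, float)
    radii = np.asarray(radii, float)
    r_orb = orbit.r_of_theta(thetas)
    relaxed = np.abs(radii - r_orb) <= rel_tol * r_orb
    if not np.any(relaxed):
        raise ValueError("oscillator never relaxed to within tolerance of the orbit")
    i0 = int(np.argmax(relaxed))
    # distance (in radians) still to travel to the next pi/2 crossing
    gap = np.mod(np.pi / 2 - thetas, TWO_PI)
    target = thetas[i0] + gap[i0]
    for i in range(i0, times.size - 1):
        if thetas[i + 1] >= target:
            frac = (target - thetas[i]) / (thetas[i + 1] - thetas[i])
            return float(times[i] + frac * (times[i + 1] - times[i]))
    raise ValueError("no peak crossing within the provided trajectory")


def simulate_entrainment_dynamic(
    geom: OrbitGeometry,
    tau: float,
    T: float = 24.0,
    n_cycles: int = 10,
    theta0s: Sequence[float] = (0.0, np.pi),
    tol: float = np.pi / 180.0,
    dt: float = 0.01,
    relax_horizon: float = 48.0,
):
    """Entrained peak time for one day length with explicit orbit dynamics.

    Runs ``n_cycles`` light-dark cycles from each initial phase (started on
    the day orbit), switching the active orbit at dusk and dawn with the
    position preserved (coordinates recomputed about the new center).  After
    the final dawn the oscillator relaxes in daytime conditions and the peak
    time is the first crossing of theta = pi/2 after return to the orbit.
    Entrainment fails if dawn phases of the last two cycles, or of the two
    initial conditions, disagree by more than ``tol`` radians.

    Returns ``(t_pk_hours, ok)``.
    """
    day, night = geom.day_orbit, geom.night_orbit
    circular = day.is_circle and night.is_circle

    def advance(state, orbit, duration, t_mod0):
        if circular:
            return _advance_circular_segment(state, orbit, duration, geom, t_mod0), None
        times, ths, rs = integrate_relaxation(state, geom, orbit, duration, dt, t_mod0)
        return PlanarState(theta=float(ths[-1]), r=float(rs[-1])), (times, ths, rs)

    tpks, finals, penult = [], [], []
    for th0 in theta0s:
        state = PlanarState(theta=float(th0), r=float(day.r_of_theta(th0)))
        prev = None
        t_abs = 0.0
        for n in range(n_cycles):
            t_mod = 0.0 if geom.modulation_reference == "dawn" else t_abs
            state, _ = advance(state, day, tau, t_mod)
            state = PlanarState.from_xy(state.to_xy(day), night)
            t_mod = tau if geom.modulation_reference == "dawn" else t_abs + tau
            state, _ = advance(state, night, T - tau, t_mod)
            state = PlanarState.from_xy(state.to_xy(night), day)
            t_abs += T
            if n == n_cycles - 2:
                prev = state.theta
        finals.append(state.theta)
        penult.append(prev)
        t_mod = 0.0 if geom.modulation_reference == "dawn" else t_abs
        if circular and geom.eps_ratio == 0.0:
            # closed form: relax, then drift at omega to the next pi/2 crossing
            n_steps = int(round(relax_horizon / dt))
            times = np.arange(n_steps + 1) * dt
            ths = state.theta + geom.omega * times
            rs = day.radius + (state.r - day.radius) * np.exp(-geom.a * times)
        else:
            times, ths, rs = integrate_relaxation(state, geom, day, relax_horizon,
                                                  dt, t_mod)
        tpks.append(peak_time_dynamic(times, ths, rs, day))
    ok = all(abs(wrap_pi(f - p)) <= tol for f, p in zip(finals, penult))
    ok = ok and all(abs(wrap_pi(f - finals[0])) <= tol for f in finals[1:])
    return float(np.mean(tpks)), bool(ok)


# ---------------------------------------------------------------------------
# (R, X) parameter sweeps


def _slope_from_series(taus, values, unwrap_rad: bool, omega: float,
                       err_abs: Optional[float], err_frac: float = 0.10):
    """Linear slope of entrained phase/peak time vs day length, with the
    linearity mask of the grid-scan protocol."""
    taus = np.asarray(taus, float)
    if unwrap_rad:
        tpk = np.mod(np.pi / 2 - np.unwrap(np.asarray(values, float)), TWO_PI)
        tpk = np.unwrap(tpk) / omega
    else:
        # peak times carry a mod-period ambiguity across the tau series
        tpk = np.unwrap(np.asarray(values, float), period=TWO_PI / omega)
    slope, intercept = np.polyfit(taus, tpk, 1)
    resid = tpk - (slope * taus + intercept)
    mean_err = float(np.mean(np.abs(resid)))
    spread = float(np.ptp(tpk))
    nonlinear = mean_err > err_frac * spread
    if err_abs is not None:
        nonlinear = nonlinear and mean_err > err_abs
    return (np.nan, mean_err) if nonlinear else (float(slope), mean_err)


def slope_over_grid(
    R_grid,
    X_grid,
    taus=np.arange(6.0, 18.1, 1.0),
    variant: str = "instant",
    a: Optional[float] = None,
    rho_day: float = 1.0,
    rho_night: float = 1.0,
    eps_ratio: float = 0.0,
    T: float = 24.0,
    n_cycles: Optional[int] = None,
    dt: float = 0.01,
) -> dict:
    """Slope m of entrained phase vs day length over an (R, X) grid.

    For every geometry the entrainment simulations are run across the
    day-length grid; (R, X) cells where any day length fails the entrainment
    criteria, or where the phase/peak-time dependence on day length is
    non-linear (mean absolute fit error above 10% of the spread; dynamical
    variants additionally require the error to exceed 0.5 h), are masked
    with NaN.  Cycle counts default to 30 (instant), 10 (attraction and
    velocity variants), and 4 (ellipse).

    Returns ``{"R": ..., "X": ..., "m": 2-D array (R x X), "mask": ...}``.
    """
    if variant not in ("instant", "attraction", "ellipse", "velocity"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant != "instant" and a is None:
        a = 1.0
    if n_cycles is None:
        n_cycles = {"instant": 30, "attraction": 10, "ellipse": 4, "velocity": 10}[variant]
    R_grid = np.asarray(R_grid, float)
    X_grid = np.asarray(X_grid, float)
    m = np.full((R_grid.size, X_grid.size), np.nan)
    for i, R in enumerate(R_grid):
        for j, X in enumerate(X_grid):
            if variant == "instant":
                geom = OrbitGeometry(R=R, X=X)
                vals, ok_all = [], True
                for tau in taus:
                    phase, ok = simulate_entrainment_instant(
                        geom, tau, T=T, n_cycles=n_cycles)
                    ok_all = ok_all and ok
                    vals.append(phase)
                if ok_all:
                    m[i, j], _ = _slope_from_series(
                        taus, vals, unwrap_rad=True, omega=geom.omega, err_abs=None)
            else:
                geom = OrbitGeometry(
                    R=R, X=X, a=a,
                    rho_day=rho_day if variant == "ellipse" else 1.0,
                    rho_night=rho_night if variant == "ellipse" else 1.0,
                    eps_ratio=eps_ratio if variant == "velocity" else 0.0,
                )
                vals, ok_all = [], True
                for tau in taus:
                    try:
                        tpk, ok = simulate_entrainment_dynamic(
                            geom, tau, T=T, n_cycles=n_cycles, dt=dt)
                    except ValueError:
                        ok = False
                        tpk = np.nan
                    ok_all = ok_all and ok
                    vals.append(tpk)
                if ok_all:
                    m[i, j], _ = _slope_from_series(
                        taus, vals, unwrap_rad=False, omega=geom.omega, err_abs=0.5)
    return {"R": R_grid, "X": X_grid, "m": m, "mask": np.isnan(m)}
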