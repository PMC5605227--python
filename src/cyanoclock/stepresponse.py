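"""Dawn/dusk step-response functions from step-perturbation experiments.

A step-response function maps the clock phase at which an environmental
transition occurs to the instantaneous phase shift it causes: L(theta) for
dark-to-light (dawn) steps, D(theta) for light-to-dark (dusk) steps.  Both
are 1-cycle periodic with winding number 0 (no shift ever reaches a full
cycle).  This module measures them from control/stepped trajectory pairs,
assembles periodic interpolants, linearizes them over the phase range used
during entrainment, and propagates uncertainty by non-parametric bootstrap.

Sign convention: the linear forms are written ``L(theta) = -l*(theta -
theta_L)`` and ``D(theta) = -d*(theta - theta_D)`` with *positive* stored
slopes ``l`` and ``d`` (the raw regression slope is negated), matching the
entrained-slope formula m(l, d) of :mod:`cyanoclock.lineartheory`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._phase import TWO_PI, wrap_cycles, wrap_half_cycles
from .rhythms import (
    SinusoidFit,
    TimeSeriesTrajectory,
    fit_sinusoids_shared_period,
    normalize_trajectory,
)

__all__ = [
    "StepResponseFunction",
    "LinearStepParams",
    "StepTrajectory",
    "StepExperimentSet",
    "StepResponseMeasurement",
    "BootstrapEnsemble",
    "step_phase_shift",
    "assemble_step_response",
    "linearize_step_response",
    "measure_step_responses",
    "bootstrap_master_dataset",
    "bootstrap_slopes",
    "polarization_to_phosphorylation_phase",
]

HOURS_PER_CYCLE = 24.0  # CT labeling convention: CT 0 = KaiC phosphorylation trough


# ---------------------------------------------------------------------------
# step-response function containers


@dataclass
class StepResponseFunction:
    """Tabulated periodic phase-shift function (dawn L or dusk D).

    ``phases`` are node phases in cycles, sorted in [0, 1); ``shifts`` the
    corresponding phase shifts in cycles, all below one cycle in magnitude.
    Evaluation linearly interpolates with exact 1-cycle periodic
    continuation (the wrap-around segment interpolates from the last node to
    the first node shifted by one cycle).
    """

    kind: str  # "dawn" or "dusk"
    phases: np.ndarray
    shifts: np.ndarray

    def __post_init__(self):
        if self.kind not in ("dawn", "dusk"):
            raise ValueError(f"kind must be 'dawn' or 'dusk', got {self.kind!r}")
        self.phases = np.asarray(self.phases, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.phases.shape != self.shifts.shape or self.phases.ndim != 1:
            raise ValueError("phases and shifts must be 1-D arrays of equal length")
        if self.phases.size < 2:
            raise ValueError("need at least two nodes")
        if np.any(self.phases < 0) or np.any(self.phases >= 1):
            raise ValueError("node phases must lie in [0, 1)")
        if np.any(np.diff(self.phases) <= 0):
            raise ValueError("node phases must be strictly increasing")
        if np.any(np.abs(self.shifts) >= 1):
            raise ValueError("shifts must be below one cycle (winding number 0)")

    def __call__(self, theta):
        th = wrap_cycles(np.asarray(theta, dtype=float))
        xp = np.concatenate(([self.phases[-1] - 1.0], self.phases, [self.phases[0] + 1.0]))
        fp = np.concatenate(([self.shifts[-1]], self.shifts, [self.shifts[0]]))
        out = np.interp(th, xp, fp)
        return out if out.ndim else float(out)


@dataclass
class LinearStepParams:
    """Piecewise-linear (single-breakpoint) step-response approximation.

    Represents ``F(theta) = -slope * (theta - anchor)`` extended over the
    whole cycle with the same slope and a single one-cycle offset jump at
    ``breakpoint``, which keeps the function periodic with winding 0.  The
    object is callable with phases in cycles (scalar or array).
    """

    kind: str  # "dawn" or "dusk"
    slope: float  # positive l or d of L = -l*(theta - theta_L)
    anchor: float  # cycles, in [0, 1)
    breakpoint: float  # cycles, in [0, 1)
    ct_range: Optional[tuple[float, float]] = None  # linearization range, CT hours

    def __post_init__(self):
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        self.anchor = float(wrap_cycles(self.anchor))
        self.breakpoint = float(wrap_cycles(self.breakpoint))

    def __call__(self, theta):
        th = wrap_cycles(np.asarray(theta, dtype=float))
        # unroll onto the branch [breakpoint, breakpoint + 1)
        u = np.mod(th - self.breakpoint, 1.0) + self.breakpoint
        anchor = self.anchor if self.anchor >= self.breakpoint else self.anchor + 1.0
        out = -self.slope * (u - anchor)
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# elementary operations


def step_phase_shift(
    control_fit: SinusoidFit,
    perturbed_fit: SinusoidFit,
    t_step: float,
    T_control: Optional[float] = None,
    T_perturbed: Optional[float] = None,
) -> tuple[float, float]:
    """Phase of a step perturbation and the shift it caused, in cycles.

    The phase at which the step occurred is read off the *control* fit at the
    step time, ``theta = (2*pi*t/T_con - phi_con)/(2*pi)``; the shift is the
    perturbed reaction's apparent phase at the same instant minus the control
    phase, wrapped to (-0.5, 0.5].  Evaluating both fits at the step time
    disentangles the instantaneous shift from the period change across the
    step.  Periods default to each fit's own (shared-fit) period.
    """
    if control_fit is None:
        raise ValueError("missing control fit")
    T_con = control_fit.period if T_control is None else T_control
    T_pert = perturbed_fit.period if T_perturbed is None else T_perturbed
    theta_con = wrap_cycles(t_step / T_con - control_fit.phase / TWO_PI)
    theta_pert = wrap_cycles(t_step / T_pert - perturbed_fit.phase / TWO_PI)
    return float(theta_con), float(wrap_half_cycles(theta_pert - theta_con))


def assemble_step_response(
    measurements: Sequence[tuple[float, float]],
    kind: str,
    atol: float = 1e-9,
) -> StepResponseFunction:
    """Build a periodic interpolant from (phase, shift) measurements.

    Exact duplicates are merged; distinct shifts at the same phase are an
    error (the function would be multivalued).
    """
    meas = [(float(wrap_cycles(th)), float(dth)) for th, dth in measurements]
    meas.sort()
    phases, shifts = [], []
    conflicts = []
    for th, dth in meas:
        if phases and abs(th - phases[-1]) <= atol:
            if abs(dth - shifts[-1]) > atol:
                conflicts.append((th, shifts[-1], dth))
            continue
        phases.append(th)
        shifts.append(dth)
    if conflicts:
        raise ValueError(f"conflicting shifts at duplicate phases: {conflicts}")
    return StepResponseFunction(kind=kind, phases=np.asarray(phases),
                                shifts=np.asarray(shifts))


def _nodes_in_ct_range(F: StepResponseFunction, ct_range_hours):
    lo, hi = (ct_range_hours[0] / HOURS_PER_CYCLE, ct_range_hours[1] / HOURS_PER_CYCLE)
    if not lo < hi:
        raise ValueError(f"empty linearization range {ct_range_hours}")
    th_sel, dth_sel = [], []
    for th, dth in zip(F.phases, F.shifts):
        for cand in (th, th + 1.0):
            if lo - 1e-12 <= cand <= hi + 1e-12:
                th_sel.append(cand)
                dth_sel.append(dth)
                break
    return np.asarray(th_sel), np.asarray(dth_sel)


def linearize_step_response(
    F: StepResponseFunction,
    ct_range_hours: tuple[float, float],
    breakpoint: Optional[float] = None,
) -> LinearStepParams:
    """Fit a line to the nodes inside a CT range and extend it periodically.

    The conventional ranges are CT 6-22 h for dusk (D) functions and
    CT 18-34 h for dawn (L) functions, centered on the phases the oscillator
    occupies during diurnal entrainment.  The regression is unweighted; the
    stored slope is the negated raw slope (positive ``l``/``d`` convention).
    The breakpoint defaults to the phase diametrically opposite the midpoint
    of the linearization range.
    """
    th, dth = _nodes_in_ct_range(F, ct_range_hours)
    if th.size < 3:
        raise ValueError(
            f"only {th.size} nodes inside CT range {ct_range_hours}; need >= 3"
        )
    s, c = np.polyfit(th, dth, 1)
    slope = -float(s)
    if abs(slope) > 1e-12:
        anchor = wrap_cycles(float(c) / slope)
    else:
        anchor = wrap_cycles(0.5 * (th.min() + th.max()))
    mid = 0.5 * (ct_range_hours[0] + ct_range_hours[1]) / HOURS_PER_CYCLE
    bp = wrap_cycles(mid + 0.5) if breakpoint is None else wrap_cycles(breakpoint)
    return LinearStepParams(kind=F.kind, slope=slope, anchor=float(anchor),
                            breakpoint=float(bp), ct_range=tuple(ct_range_hours))


def bootstrap_slopes(
    phases,
    shifts,
    n_samples: int = 500,
    rng: Optional[np.random.Generator] = None,
    min_unique: int = 3,
    max_attempts_factor: int = 1000,
) -> np.ndarray:
    """Bootstrap distribution of the (positive-convention) linear slope.

    Resamples the in-region (phase, shift) points with replacement,
    discarding draws with fewer than ``min_unique`` distinct phases, until
    ``n_samples`` slopes are collected.
    """
    phases = np.asarray(phases, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    if np.unique(phases).size < min_unique:
        raise ValueError(f"fewer than {min_unique} unique phases in region")
    rng = np.random.default_rng() if rng is None else rng
    out = []
    attempts = 0
    while len(out) < n_samples:
        attempts += 1
        if attempts > max_attempts_factor * n_samples:
            raise RuntimeError("bootstrap resampling failed to find valid draws")
        idx = rng.integers(0, phases.size, size=phases.size)
        if np.unique(phases[idx]).size < min_unique:
            continue
        s, _ = np.polyfit(phases[idx], shifts[idx], 1)
        out.append(-float(s))
    return np.asarray(out)


def polarization_to_phosphorylation_phase(theta):
    """Convert polarization-reporter phase to KaiC phosphorylation phase.

    The phosphorylation rhythm lags the KaiB-KaiC binding (polarization)
    reporter by about a third of a cycle (2*pi/3), so the phosphorylation
    phase is the polarization phase minus 1/3 cycle, wrapped.
    """
    return wrap_cycles(np.asarray(theta, dtype=float) - 1.0 / 3.0)


# ---------------------------------------------------------------------------
# experiment sets and end-to-end measurement


@dataclass
class StepTrajectory:
    """One member of a step experiment: a control or stepped reaction.

    ``condition`` is the buffer condition of the data that get fitted: for a
    stepped reaction this is the post-step condition ("night" for a
    step-down, "day" for a step-up); for controls it is the constant
    condition the reaction stayed in.
    """

    traj: TimeSeriesTrajectory
    role: str  # "control" or "stepped"
    condition: str  # "day" or "night"
    step_time: Optional[float] = None
    direction: Optional[str] = None  # "up" or "down" for stepped members

    def __post_init__(self):
        if self.role not in ("control", "stepped"):
            raise ValueError(f"bad role {self.role!r}")
        if self.condition not in ("day", "night"):
            raise ValueError(f"bad condition {self.condition!r}")
        if self.role == "stepped":
            if self.step_time is None or self.direction not in ("up", "down"):
                raise ValueError("stepped members need step_time and direction")


@dataclass
class StepExperimentSet:
    """Master dataset of step-perturbation trajectories plus controls."""

    members: list[StepTrajectory]
    exclusion_window: float = 16.0  # hours of post-step data excluded from fits

    def __post_init__(self):
        if self.exclusion_window < 0:
            raise ValueError("exclusion window must be >= 0")

    def controls(self, condition: str) -> list[StepTrajectory]:
        return [m for m in self.members if m.role == "control" and m.condition == condition]

    def stepped(self, direction: str) -> list[StepTrajectory]:
        return [m for m in self.members if m.role == "stepped" and m.direction == direction]


@dataclass
class StepResponseMeasurement:
    """Point estimate of L, D, and the day/night periods from one dataset."""

    L: StepResponseFunction
    D: StepResponseFunction
    T_day: float
    T_night: float
    up_measurements: list[tuple[float, float]]
    down_measurements: list[tuple[float, float]]
    L_lin: Optional[LinearStepParams] = None
    D_lin: Optional[LinearStepParams] = None

    @property
    def freq_ratio(self) -> float:
        """omega_D / omega_L = T_day / T_night."""
        return self.T_day / self.T_night


def _fit_trimmed(members, exclusion_window, period_bounds):
    """Trim post-step transients, normalize, and fit with a shared period."""
    trajs = []
    for m in members:
        tr = m.traj
        if m.role == "stepped":
            keep = tr.times >= m.step_time + exclusion_window
            tr = TimeSeriesTrajectory(
                times=tr.times[keep], values=tr.values[keep], light=tr.light[keep],
                series_id=tr.series_id,
            )
        trajs.append(normalize_trajectory(tr, discard_after_lights_on=0.0))
    return fit_sinusoids_shared_period(trajs, period_bounds=period_bounds)


def measure_step_responses(
    expset: StepExperimentSet,
    period_bounds: tuple[float, float] = (20.0, 30.0),
    linearize: bool = True,
    ct_range_L: tuple[float, float] = (18.0, 34.0),
    ct_range_D: tuple[float, float] = (6.0, 22.0),
    peak_phase: float = 0.5,
) -> StepResponseMeasurement:
    """Extract L and D from a step experiment set.

    Day-condition data (step-up reactions after the step, plus the day
    control) are fit jointly for ``T_day``; night-condition data for
    ``T_night``.  Each step's phase is evaluated on its pre-step control at
    the step time, and the shift is the perturbed-minus-control phase there.

    ``peak_phase`` anchors the raw fit phases to the clock convention: it is
    the clock phase (cycles) at which the reporter signal peaks, 0.5 for a
    reporter peaking at the phosphorylation peak.  The raw formula
    ``theta = t/T - phi/(2*pi)`` places the fitted sinusoid's peak at 0.25
    cycles, so all step phases are offset by ``peak_phase - 0.25`` (shift
    values are unaffected).
    """
    day_members = [m for m in expset.members if m.condition == "day"]
    night_members = [m for m in expset.members if m.condition == "night"]
    if not expset.controls("day") or not expset.controls("night"):
        raise ValueError("need at least one control in each condition")
    T_day, day_fits = _fit_trimmed(day_members, expset.exclusion_window, period_bounds)
    T_night, night_fits = _fit_trimmed(night_members, expset.exclusion_window, period_bounds)
    fits = {id(m): f for m, f in zip(day_members, day_fits)}
    fits.update({id(m): f for m, f in zip(night_members, night_fits)})

    def control_fit(condition):
        # average not needed: use the first control in that condition
        return fits[id(expset.controls(condition)[0])]

    offset = peak_phase - 0.25
    up_meas, down_meas = [], []
    for m in expset.stepped("up"):
        # step-up: pre-step condition night -> phase from the night control
        th, dth = step_phase_shift(
            control_fit("night"), fits[id(m)], m.step_time,
            T_control=T_night, T_perturbed=T_day,
        )
        up_meas.append((float(wrap_cycles(th + offset)), dth))
    for m in expset.stepped("down"):
        th, dth = step_phase_shift(
            control_fit("day"), fits[id(m)], m.step_time,
            T_control=T_day, T_perturbed=T_night,
        )
        down_meas.append((float(wrap_cycles(th + offset)), dth))
    if len(up_meas) < 2 or len(down_meas) < 2:
        raise ValueError("need at least two step-up and two step-down measurements")
    L = assemble_step_response(up_meas, kind="dawn")
    D = assemble_step_response(down_meas, kind="dusk")
    result = StepResponseMeasurement(
        L=L, D=D, T_day=float(T_day), T_night=float(T_night),
        up_measurements=up_meas, down_measurements=down_meas,
    )
    if linearize:
        try:
            result.L_lin = linearize_step_response(L, ct_range_L)
            result.D_lin = linearize_step_response(D, ct_range_D)
        except ValueError as err:
            warnings.warn(f"linearization skipped: {err}")
    return result


@dataclass
class BootstrapEnsemble:
    """Resampled step-response measurements with their generating seed."""

    members: list[StepResponseMeasurement]
    n_requested: int
    seed: Optional[int]
    n_redraws: int = 0

    def slopes(self) -> tuple[np.ndarray, np.ndarray]:
        """(l, d) arrays across ensemble members that linearized."""
        l = np.array([m.L_lin.slope for m in self.members if m.L_lin is not None])
        d = np.array([m.D_lin.slope for m in self.members if m.D_lin is not None])
        return l, d

    def freq_ratios(self) -> np.ndarray:
        return np.array([m.freq_ratio for m in self.members])

    def evaluate(self, kind: str, theta_grid) -> np.ndarray:
        """Ensemble member values of L or D on a phase grid (members x grid)."""
        funcs = [m.L if kind == "dawn" else m.D for m in self.members]
        return np.vstack([f(theta_grid) for f in funcs])


def bootstrap_master_dataset(
    master: StepExperimentSet,
    n: int = 1000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    min_phases: int = 3,
    **measure_kwargs,
) -> BootstrapEnsemble:
    """Bootstrap L/D uncertainty by resampling the entire master dataset.

    Trajectories are sampled with replacement from the pooled master set (not
    per condition), so both the step-phase errors and the shift errors
    propagate.  Resamples missing a control in either condition, or with
    fewer than ``min_phases`` distinct step phases in either direction, are
    redrawn and counted in ``n_redraws``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    members = master.members
    ensemble: list[StepResponseMeasurement] = []
    n_redraws = 0
    attempts_cap = 1000 * n + 1000
    attempts = 0
    while len(ensemble) < n:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError("bootstrap failed to draw valid resamples")
        idx = rng.integers(0, len(members), size=len(members))
        resampled = [members[i] for i in idx]
        sub = StepExperimentSet(members=resampled,
                                exclusion_window=master.exclusion_window)
        n_up = len({m.step_time for m in sub.stepped("up")})
        n_down = len({m.step_time for m in sub.stepped("down")})
        if (not sub.controls("day") or not sub.controls("night")
                or n_up < min_phases or n_down < min_phases):
            n_redraws += 1
            continue
        # duplicated members up-weight the shared-period fits (the point of
        # resampling); their identical (phase, shift) pairs merge at assembly
        ensemble.append(measure_step_responses(sub, **measure_kwargs))
    return BootstrapEnsemble(members=ensemble, n_requested=n, seed=seed,
                             n_redraws=n_redraws)
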