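"""Rhythm time-series normalization and phase/period estimation.

Tools for driven circadian reporter rhythms: z-score normalization with
masking of dark samples and post-lights-on transients, sinusoidal regression
(single-series and shared-period), local parabolic peak fitting, outlier
rejection, Kendall-tau waveform comparison between driven and free-running
windows, dark-pulse phase-shift extraction, and weighted linear regression
with known errors in the dependent variable.

Sinusoids are parameterized as ``A*sin(2*pi*t/T - phi) + b*t + C``.  For a
fixed period the amplitude/phase pair is linear in ``(p, q)`` with
``A*sin(x - phi) = p*sin(x) + q*cos(x)``, ``p = A*cos(phi)``,
``q = -A*sin(phi)``; fits therefore profile out all linear parameters and
search only over the period (variable projection), which finds the global
least-squares optimum on these models without multi-start heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal, stats

from ._phase import TWO_PI, circular_mean_cycles, wrap_cycles, wrap_interval

__all__ = [
    "TimeSeriesTrajectory",
    "SinusoidFit",
    "PeakEstimate",
    "PhaseShiftMeasurement",
    "WeightedLineFit",
    "normalize_trajectory",
    "fit_sinusoid",
    "fit_sinusoids_shared_period",
    "fit_peaks_parabolic",
    "reject_outlier_fits",
    "kendall_entrainment_similarity",
    "dark_pulse_phase_shift",
    "regress_slope_with_errors",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TimeSeriesTrajectory:
    """One recorded or synthetic rhythm with light/dark annotation.

    Parameters
    ----------
    times :
        Sample times in hours since experiment start, strictly increasing.
    values :
        Signal in arbitrary units (or normalized units after
        :func:`normalize_trajectory`).
    light :
        Per-sample flag, True when the lights were on (or the reaction was in
        day-condition buffer) at that sample.
    series_id :
        Label used in error messages and exported tables.
    included :
        Per-sample analysis mask.  ``None`` means "all samples"; the
        normalization step replaces it with the masking-aware selection.
    schedule :
        Optional link to the :class:`~cyanoclock.phasemodel.DrivingSchedule`
        that produced the trace.
    """

    times: np.ndarray
    values: np.ndarray
    light: np.ndarray
    series_id: str = ""
    included: Optional[np.ndarray] = None
    schedule: object = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.light = np.asarray(self.light, dtype=bool)
        if not (self.times.shape == self.values.shape == self.light.shape):
            raise ValueError(
                f"series {self.series_id!r}: times/values/light lengths differ"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"series {self.series_id!r}: times must be strictly increasing")
        if self.included is not None:
            self.included = np.asarray(self.included, dtype=bool)
            if self.included.shape != self.times.shape:
                raise ValueError(f"series {self.series_id!r}: included mask length differs")

    @property
    def mask(self) -> np.ndarray:
        """Effective analysis mask (all-True when no mask has been set)."""
        if self.included is None:
            return np.ones_like(self.light, dtype=bool)
        return self.included

    def retained(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) of samples passing the analysis mask."""
        m = self.mask
        return self.times[m], self.values[m]

    def dawn_times(self) -> np.ndarray:
        """Times of dark-to-light transitions inferred from the flags."""
        lit = self.light.astype(int)
        idx = np.nonzero(np.diff(lit) == 1)[0] + 1
        return self.times[idx]


@dataclass
class SinusoidFit:
    """Least-squares sinusoid parameters for one trajectory."""

    amplitude: float
    period: float
    phase: float  # radians, wrapped to (-pi, pi]
    trend: float  # per hour; 0.0 when the linear term was not fit
    baseline: float
    squared_error: float
    n_points: int
    series_id: str = ""
    converged: bool = True

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.amplitude * np.sin(TWO_PI * t / self.period - self.phase)
            + self.trend * t
            + self.baseline
        )

    def phase_cycles_at(self, t) -> np.ndarray:
        """Instantaneous clock phase (2*pi*t/T - phi)/(2*pi), wrapped to [0,1)."""
        t = np.asarray(t, dtype=float)
        return wrap_cycles(t / self.period - self.phase / TWO_PI)

    def peak_time_near(self, t_ref: float) -> float:
        """Time of the fitted sinusoid's maximum closest to ``t_ref``.

        Peaks occur where ``2*pi*t/T - phi = pi/2 (mod 2*pi)``.
        """
        base = self.period * (self.phase / TWO_PI + 0.25)
        k = np.round((t_ref - base) / self.period)
        return float(base + k * self.period)


@dataclass
class PeakEstimate:
    """Peak times from local parabolic regression."""

    peak_times: np.ndarray
    period_estimate: float  # mean successive peak spacing; nan with < 2 peaks
    window: float  # full width of each fit window, hours
    n_rejected: int = 0

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size >= 2 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak_times must be increasing")


@dataclass
class PhaseShiftMeasurement:
    """Dark-pulse response: peak-time shift and phase at perturbation."""

    t_perturbation: float  # pulse start, hours
    phase_at_perturbation: float  # cycles in [0, 1)
    delta_peak_time: float  # hours, wrapped to (-T/2, T/2]
    sd: float  # replicate SD of the peak-time shift, hours
    n_perturbed: int = 0
    n_control: int = 0


# ---------------------------------------------------------------------------
# normalization


def normalize_trajectory(
    traj: TimeSeriesTrajectory, discard_after_lights_on: float = 2.5
) -> TimeSeriesTrajectory:
    """Mask dark and post-lights-on samples, then z-score the retained ones.

    All samples recorded in the dark are excluded, as are samples within
    ``discard_after_lights_on`` hours after any dark-to-light transition
    (reporter masking transients).  The whole trace is affinely rescaled so
    the retained samples have mean 0 and standard deviation 1.

    Raises
    ------
    ValueError
        If fewer than 4 samples survive masking, or the retained signal has
        zero variance.
    """
    keep = traj.light.copy()
    if discard_after_lights_on > 0:
        for t0 in traj.dawn_times():
            keep &= ~((traj.times >= t0) & (traj.times < t0 + discard_after_lights_on))
    keep &= traj.mask
    n = int(keep.sum())
    if n < 4:
        raise ValueError(
            f"series {traj.series_id!r}: only {n} samples retained after masking"
        )
    mu = float(traj.values[keep].mean())
    sd = float(traj.values[keep].std(ddof=0))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError(f"series {traj.series_id!r}: zero variance in retained signal")
    return replace(traj, values=(traj.values - mu) / sd, included=keep)


# ---------------------------------------------------------------------------
# sinusoidal regression (variable projection over the period)


def _design(t: np.ndarray, period: float, include_trend: bool) -> np.ndarray:
    x = TWO_PI * t / period
    cols = [np.sin(x), np.cos(x), np.ones_like(t)]
    if include_trend:
        cols.append(t)
    return np.column_stack(cols)


def _linear_solve(t, y, period, include_trend):
    M = _design(t, period, include_trend)
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ coef
    return coef, float(resid @ resid)


def _coef_to_fit(coef, period, include_trend, sq_err, n, series_id):
    p, q, c = coef[0], coef[1], coef[2]
    b = float(coef[3]) if include_trend else 0.0
    amp = float(np.hypot(p, q))
    phi = float(np.arctan2(-q, p)) if amp > 0 else 0.0
    if phi <= -np.pi:  # arctan2 returns [-pi, pi]; convention is (-pi, pi]
        phi += TWO_PI
    return SinusoidFit(
        amplitude=amp,
        period=float(period),
        phase=phi,
        trend=b,
        baseline=float(c),
        squared_error=sq_err,
        n_points=int(n),
        series_id=series_id,
    )


def _minimize_period(cost, lo, hi, n_grid):
    grid = np.linspace(lo, hi, n_grid)
    costs = [cost(T) for T in grid]
    i = int(np.argmin(costs))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    if a == b:
        return float(grid[i])
    res = optimize.minimize_scalar(cost, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x) if res.fun <= costs[i] else float(grid[i])


def fit_sinusoid(
    traj: TimeSeriesTrajectory,
    period_bounds: tuple[float, float] = (23.0, 25.0),
    include_trend: bool = False,
    fixed_period: Optional[float] = None,
    n_grid: int = 41,
) -> SinusoidFit:
    """Least-squares sinusoid fit with the period constrained to bounds.

    The default bounds (23, 25) h are the conventional constraint for
    free-running reporter rhythms near 24 h; pass ``fixed_period`` to pin the
    period instead (e.g. to a 24 h imposed metabolic cycle).
    """
    t, y = traj.retained()
    if t.size < 4:
        raise ValueError(f"series {traj.series_id!r}: too few samples to fit")
    if fixed_period is not None:
        coef, sq = _linear_solve(t, y, fixed_period, include_trend)
        return _coef_to_fit(coef, fixed_period, include_trend, sq, t.size, traj.series_id)
    lo, hi = period_bounds
    if not lo < hi:
        raise ValueError(f"invalid period bounds {period_bounds}")

    def cost(T):
        return _linear_solve(t, y, T, include_trend)[1]

    T = _minimize_period(cost, lo, hi, n_grid)
    coef, sq = _linear_solve(t, y, T, include_trend)
    fit = _coef_to_fit(coef, T, include_trend, sq, t.size, traj.series_id)
    if not np.isfinite(fit.squared_error):
        fit.converged = False
    return fit


def fit_sinusoids_shared_period(
    trajs: Sequence[TimeSeriesTrajectory],
    period_bounds: tuple[float, float] = (20.0, 30.0),
    include_trend: bool = False,
    n_grid: int = 61,
) -> tuple[float, list[SinusoidFit]]:
    """Joint sinusoid fit with one period shared across all series.

    Amplitude, phase, and baseline (and trend, if requested) remain
    independent per series; the shared period minimizes the summed residual
    cost.  Used for replicate in vitro reactions in one buffer condition.
    """
    if len(trajs) == 0:
        raise ValueError("need at least one trajectory")
    data = [traj.retained() for traj in trajs]
    lo, hi = period_bounds
    if not lo < hi:
        raise ValueError(f"invalid period bounds {period_bounds}")

    def cost(T):
        return sum(_linear_solve(t, y, T, include_trend)[1] for t, y in data)

    T = _minimize_period(cost, lo, hi, n_grid)
    fits = []
    for traj, (t, y) in zip(trajs, data):
        coef, sq = _linear_solve(t, y, T, include_trend)
        fits.append(_coef_to_fit(coef, T, include_trend, sq, t.size, traj.series_id))
    return T, fits


# ---------------------------------------------------------------------------
# parabolic peak fitting


def fit_peaks_parabolic(
    traj: TimeSeriesTrajectory,
    window: float = 6.0,
    min_separation: float = 12.0,
) -> PeakEstimate:
    """Estimate peak times by fitting parabolas in windows around maxima.

    Candidate peaks are local maxima of a 3-sample moving median with a
    minimum separation of ``min_separation`` hours (default half a circadian
    cycle); each candidate is refined by a quadratic fit to samples within
    ``window``/2 hours of it, taking the vertex as the peak time.  Vertices
    falling outside their window, or windows without curvature, reject the
    candidate with a warning.
    """
    t, y = traj.retained()
    if t.size < 3:
        raise ValueError(f"series {traj.series_id!r}: too few samples for peak fitting")
    med = signal.medfilt(y, kernel_size=3)
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(min_separation / dt)))
    idx, _ = signal.find_peaks(med, distance=distance)
    peaks = []
    n_rej = 0
    for i in idx:
        tc = t[i]
        sel = np.abs(t - tc) <= window / 2.0
        if sel.sum() < 3:
            n_rej += 1
            warnings.warn(f"series {traj.series_id!r}: too few samples near t={tc:.2f}")
            continue
        a, b, _c = np.polyfit(t[sel], y[sel], 2)
        if a >= 0:
            n_rej += 1
            warnings.warn(f"series {traj.series_id!r}: no local maximum near t={tc:.2f}")
            continue
        vertex = -b / (2.0 * a)
        if abs(vertex - tc) > window / 2.0:
            n_rej += 1
            warnings.warn(
                f"series {traj.series_id!r}: vertex {vertex:.2f} outside window at t={tc:.2f}"
            )
            continue
        peaks.append(vertex)
    peaks = np.sort(np.asarray(peaks))
    period = float(np.mean(np.diff(peaks))) if peaks.size >= 2 else float("nan")
    return PeakEstimate(peak_times=peaks, period_estimate=period, window=window,
                        n_rejected=n_rej)


# ---------------------------------------------------------------------------
# quality control and waveform comparison


def reject_outlier_fits(
    fits: Sequence[SinusoidFit], threshold: float = 10.0
) -> tuple[list[SinusoidFit], int]:
    """Drop fits whose residual squared error exceeds ``threshold``.

    The default of 10 (normalized units) is the conventional cutoff for
    96-well reporter plates, where dead or noisy wells produce large
    residuals.  Returns (kept fits, number rejected); raises if nothing
    survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept = [f for f in fits if f.squared_error <= threshold]
    n_rej = len(fits) - len(kept)
    if not kept:
        raise ValueError("all fits rejected as outliers")
    return kept, n_rej


def kendall_entrainment_similarity(
    traj: TimeSeriesTrajectory,
    schedule,
    discard_after_lights_on: float = 2.5,
    atol: float = 1e-9,
) -> np.ndarray:
    """Kendall rank correlation between each driven day and the release window.

    For each entraining cycle, daytime samples (after the masking window) are
    compared at matching times-after-dawn with the corresponding window after
    release into constant conditions.  Sampling grids must match exactly; no
    interpolation is performed.  Uses the tie-adjusted tau-b statistic.
    """
    release = schedule.release_time
    taus = []
    for k in range(schedule.n_cycles):
        day_lo = k * schedule.T + discard_after_lights_on
        day_hi = k * schedule.T + schedule.tau
        rel_lo = release + discard_after_lights_on
        rel_hi = release + schedule.tau
        m_day = (traj.times >= day_lo) & (traj.times < day_hi) & traj.mask
        m_rel = (traj.times >= rel_lo) & (traj.times < rel_hi) & traj.mask
        t_day = traj.times[m_day] - k * schedule.T
        t_rel = traj.times[m_rel] - release
        if t_day.size != t_rel.size or t_day.size == 0 or np.any(
            np.abs(t_day - t_rel) > atol
        ):
            raise ValueError(
                f"series {traj.series_id!r}: sampling grids of cycle {k} and the "
                "release window do not match"
            )
        res = stats.kendalltau(traj.values[m_day], traj.values[m_rel])
        taus.append(res.statistic)
    if not taus:
        raise ValueError("schedule has no entraining cycles")
    return np.asarray(taus)


# ---------------------------------------------------------------------------
# dark-pulse phase shifts


def _mean_peak_times(fits: Sequence[SinusoidFit], t_ref: float, period: float):
    """Replicate peak times near t_ref, wrapped to one branch before averaging."""
    first = fits[0].peak_time_near(t_ref)
    pk = np.array([first] + [
        first + wrap_interval(f.peak_time_near(t_ref) - first, period) for f in fits[1:]
    ])
    return float(pk.mean()), float(pk.std(ddof=1)) if pk.size > 1 else 0.0


def dark_pulse_phase_shift(
    perturbed_fits: Sequence[SinusoidFit],
    control_fits: Sequence[SinusoidFit],
    t_pulse_start: float,
    pulse_duration: float,
    window: tuple[float, float] = (36.0, 48.0),
) -> PhaseShiftMeasurement:
    """Peak-time shift caused by a dark pulse, and the phase it hit.

    ``delta_peak_time`` is the difference of replicate-mean peak times
    (perturbed minus control) evaluated near the center of the analysis
    window, measured ``window`` hours after the end of the pulse, and wrapped
    to (-T/2, T/2].  The clock phase at the pulse start is computed from the
    control fits as ``theta_hat = t/T_LL - (phi_LL + pi/2)/(2*pi)`` (cycles,
    phase 0 at the trough of the rhythm).
    """
    if not perturbed_fits or not control_fits:
        raise ValueError("control and perturbed fit sets must be non-empty")
    T_LL = float(np.mean([f.period for f in control_fits]))
    phi_LL = circular_mean_cycles([f.phase / TWO_PI for f in control_fits]) * TWO_PI
    t_ref = t_pulse_start + pulse_duration + 0.5 * (window[0] + window[1])
    if window[1] - window[0] <= 0:
        raise ValueError("analysis window is empty")
    pk_dp, sd_dp = _mean_peak_times(perturbed_fits, t_ref, T_LL)
    pk_ll, sd_ll = _mean_peak_times(control_fits, t_ref, T_LL)
    delta = wrap_interval(pk_dp - pk_ll, T_LL)
    theta = wrap_cycles(t_pulse_start / T_LL - (phi_LL + 0.5 * np.pi) / TWO_PI)
    return PhaseShiftMeasurement(
        t_perturbation=float(t_pulse_start),
        phase_at_perturbation=float(theta),
        delta_peak_time=float(delta),
        sd=float(np.hypot(sd_dp, sd_ll)),
        n_perturbed=len(perturbed_fits),
        n_control=len(control_fits),
    )


# ---------------------------------------------------------------------------
# weighted linear regression


@dataclass
class WeightedLineFit:
    slope: float
    slope_sd: float
    intercept: float
    intercept_sd: float
    n: int


def regress_slope_with_errors(
    x, y, sigma_y=None
) -> WeightedLineFit:
    """Straight-line fit with known errors in the dependent variable.

    With ``sigma_y`` supplied, uses the standard closed-form weighted
    least-squares estimates and their analytic standard deviations
    (independent of the residuals).  Without errors, falls back to ordinary
    least squares with residual-based standard errors (which vanish for an
    exact linear relation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0:
        raise ValueError("x values have zero spread")
    if sigma_y is not None:
        w = 1.0 / np.asarray(sigma_y, dtype=float) ** 2
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("sigma_y must be positive and finite")
        S, Sx, Sy = w.sum(), (w * x).sum(), (w * y).sum()
        Sxx, Sxy = (w * x * x).sum(), (w * x * y).sum()
        delta = S * Sxx - Sx * Sx
        slope = (S * Sxy - Sx * Sy) / delta
        intercept = (Sxx * Sy - Sx * Sxy) / delta
        return WeightedLineFit(
            slope=float(slope),
            slope_sd=float(np.sqrt(S / delta)),
            intercept=float(intercept),
            intercept_sd=float(np.sqrt(Sxx / delta)),
            n=x.size,
        )
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(((x - x.mean()) ** 2).sum())
    return WeightedLineFit(
        slope=float(slope),
        slope_sd=float(np.sqrt(s2 / sxx)),
        intercept=float(intercept),
        intercept_sd=float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))),
        n=n,
    )
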