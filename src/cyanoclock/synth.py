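"""Seeded generators for every dataset shape the analysis pipeline consumes.

Each generator evolves a ground-truth phase oscillator (known free-running
periods and dawn/dusk step responses, or a known beta model) through a
driving schedule and emits the corresponding observable with additive
Gaussian noise on the normalized scale, so that every estimation stage in
the package can be validated by parameter recovery without external data.

Emulated design features: ~24 h sinusoidal reporter rhythms sampled every
30 min with replicate noise, nighttime samples flagged dark, a post-dawn
masking transient (decaying exponential) in the first hours after lights-on,
step experiments with an instantaneous phase shift plus a period change at
the step, and PRC/wedge/seasonal designs on the grids used for the driven
in vivo experiments.  The reporter waveform is sinusoidal in phase by
default; a skewed-sine option exercises the difference between parabolic
and sinusoidal peak estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from ._phase import TWO_PI, wrap_cycles
from .lineartheory import BetaModel, predict_prc, predict_seasonal, predict_wedge
from .phasemodel import (
    DrivingSchedule,
    OscillatorParams,
    iterate_diurnal_map,
    simulate_continuous,
    simulate_dark_pulse_prc,
)
from .globalfit import ObservationSet
from .stepresponse import LinearStepParams, StepExperimentSet, StepTrajectory
from .rhythms import TimeSeriesTrajectory

__all__ = ["GroundTruth", "generate_reporter_timeseries", "generate_step_experiment",
           "generate_prc_wedge_seasonal"]


@dataclass
class GroundTruth:
    """Ground-truth model and observation parameters for the generators.

    The oscillator runs at ``params`` with step responses ``L``/``D``
    (callables in cycles; ``None`` means no shift), or — for closed-form
    response generation — a ``beta`` model.  Observation parameters follow
    the reporter experiments: half-hour sampling, 4 technical replicates,
    additive Gaussian noise (sigma on the unit-amplitude normalized scale),
    a 2.5 h masking window after lights-on with an exponentially decaying
    transient.
    """

    params: OscillatorParams = field(default_factory=OscillatorParams)
    L: Optional[Callable] = None
    D: Optional[Callable] = None
    beta: Optional[BetaModel] = None
    noise_sigma: float = 0.1
    n_replicates: int = 4
    masking_window: float = 2.5
    mask_amplitude: float = 3.0
    mask_decay: float = 1.0
    cadence: float = 0.5
    skew: float = 0.0  # waveform asymmetry; 0 = pure sinusoid

    def to_dict(self) -> dict:
        """Serializable description (linear step-response truths only)."""
        d = {
            "T_day": self.params.T_day, "T_night": self.params.T_night,
            "noise_sigma": self.noise_sigma, "n_replicates": self.n_replicates,
            "masking_window": self.masking_window,
            "mask_amplitude": self.mask_amplitude, "mask_decay": self.mask_decay,
            "cadence": self.cadence, "skew": self.skew,
        }
        for name, fn in (("L", self.L), ("D", self.D)):
            if fn is None:
                d[name] = None
            elif isinstance(fn, LinearStepParams):
                d[name] = {"kind": fn.kind, "slope": fn.slope, "anchor": fn.anchor,
                           "breakpoint": fn.breakpoint}
            else:
                raise TypeError(f"{name} truth is not serializable")
        d["beta"] = None if self.beta is None else asdict(self.beta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        def mk(entry):
            return None if entry is None else LinearStepParams(**entry)

        return cls(
            params=OscillatorParams(T_day=d["T_day"], T_night=d["T_night"]),
            L=mk(d["L"]), D=mk(d["D"]),
            beta=None if d["beta"] is None else BetaModel(**d["beta"]),
            noise_sigma=d["noise_sigma"], n_replicates=d["n_replicates"],
            masking_window=d["masking_window"], mask_amplitude=d["mask_amplitude"],
            mask_decay=d["mask_decay"], cadence=d["cadence"], skew=d["skew"],
        )

    def waveform(self, theta) -> np.ndarray:
        """Reporter signal as a function of clock phase (peak at 0.5 cycles)."""
        theta = np.asarray(theta, dtype=float)
        x = TWO_PI * theta - np.pi / 2.0
        if self.skew == 0.0:
            return np.sin(x)
        # skewed sine: compress the rise, stretch the fall
        return np.sin(x + self.skew * np.sin(x))


def generate_reporter_timeseries(
    truth: GroundTruth,
    schedule: DrivingSchedule,
    rng: np.random.Generator,
    t_end: Optional[float] = None,
    theta0: float = 0.0,
    series_prefix: str = "well",
) -> list[TimeSeriesTrajectory]:
    """Reporter rhythms under a driving schedule, one per technical replicate.

    Phase evolves by the continuous-time phase model (the sampling cadence
    doubles as the integration step, which is exact for piecewise-constant
    rates); the emitted signal is the truth's waveform of phase plus noise.
    Dark samples are emitted but flagged dark, and samples in the first
    ``masking_window`` hours after each dawn carry a decaying masking
    transient so that exclusion logic is exercised.
    """
    if t_end is None:
        t_end = schedule.release_time + 3.0 * schedule.T
    traj = simulate_continuous(theta0, truth.params, truth.L, truth.D, schedule,
                               dt=truth.cadence, t_end=t_end)
    times, light = traj.times, traj.light
    clean = truth.waveform(traj.wrapped())
    # masking transient after each dark->light transition
    transient = np.zeros_like(times)
    dawns = [0.0] + [times[i] for i in range(1, times.size)
                     if light[i] and not light[i - 1]]
    for t0 in dawns:
        sel = (times >= t0) & (times < t0 + truth.masking_window)
        transient[sel] += truth.mask_amplitude * np.exp(
            -(times[sel] - t0) / truth.mask_decay)
    out = []
    for r in range(truth.n_replicates):
        noise = rng.normal(0.0, truth.noise_sigma, size=times.size)
        out.append(TimeSeriesTrajectory(
            times=times.copy(),
            values=clean + transient + noise,
            light=light.copy(),
            series_id=f"{series_prefix}_r{r}",
            schedule=schedule,
        ))
    return out


def generate_step_experiment(
    truth: GroundTruth,
    step_times: Sequence[float],
    direction: str = "down",
    rng: Optional[np.random.Generator] = None,
    t_end: float = 96.0,
    cadence: Optional[float] = None,
    theta0: float = 0.0,
) -> StepExperimentSet:
    """In-vitro-style step-perturbation experiment with known ground truth.

    Each stepped reaction free-runs in the pre-step condition, applies the
    truth's instantaneous shift (D for a step-down, L for a step-up) at its
    step time, and continues at the post-step period.  A constant day-buffer
    control and a constant night-buffer control are included for the
    shared-period fits and step-phase evaluation.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    rng = np.random.default_rng() if rng is None else rng
    dt = truth.cadence if cadence is None else cadence
    times = np.arange(0.0, t_end + dt / 2, dt)
    light = np.ones_like(times, dtype=bool)
    omega_L, omega_D = truth.params.omega_L, truth.params.omega_D

    def emit(theta, series_id):
        values = truth.waveform(wrap_cycles(theta)) + rng.normal(
            0.0, truth.noise_sigma, size=times.size)
        return TimeSeriesTrajectory(times=times.copy(), values=values,
                                    light=light.copy(), series_id=series_id)

    members = [
        StepTrajectory(traj=emit(theta0 + omega_L * times, "control_day"),
                       role="control", condition="day"),
        StepTrajectory(traj=emit(theta0 + omega_D * times, "control_night"),
                       role="control", condition="night"),
    ]
    pre_rate = omega_L if direction == "down" else omega_D
    post_rate = omega_D if direction == "down" else omega_L
    shift_fn = truth.D if direction == "down" else truth.L
    for k, ts in enumerate(step_times):
        if not 0.0 < ts < t_end:
            raise ValueError(f"step time {ts} outside the experiment span")
        theta_step = theta0 + pre_rate * ts
        shift = 0.0 if shift_fn is None else float(shift_fn(wrap_cycles(theta_step)))
        theta = np.where(
            times < ts,
            theta0 + pre_rate * times,
            theta_step + shift + post_rate * (times - ts),
        )
        members.append(StepTrajectory(
            traj=emit(theta, f"step_{direction}_{k}"),
            role="stepped",
            condition="night" if direction == "down" else "day",
            step_time=float(ts),
            direction=direction,
        ))
    return StepExperimentSet(members=members)


def generate_prc_wedge_seasonal(
    truth: GroundTruth,
    rng: np.random.Generator,
    prc_thetas: Sequence[float] = tuple(np.arange(0.05, 1.0, 0.1)),
    prc_delta: float = 12.0,
    wedge_deltas: Sequence[float] = (8.0, 10.0, 12.0, 14.0, 16.0),
    wedge_theta: float = 0.55,
    seasonal_T: Sequence[float] = (22.0, 24.0, 26.0),
    seasonal_tau: Sequence[float] = (8.0, 10.0, 12.0, 14.0),
) -> list[ObservationSet]:
    """PRC, wedge, and seasonal observation sets from a beta-model truth.

    Responses come from the closed-form beta-model predictions when the
    truth carries a beta model, or from full phase-oscillator simulation
    (dark-pulse step decomposition and map entrainment) when it carries L/D
    step responses; each design point is observed ``n_replicates`` times
    with the truth's noise and reported as the replicate mean with its
    standard error.  The design grids default to the driven in vivo
    experiments: 12 h dark pulses across the cycle, pulse durations 8-16 h
    near subjective dusk, and entrainment to T = 22-26 h cycles with day
    lengths 8-14 h.
    """
    if truth.beta is None:
        return _simulated_prc_wedge_seasonal(
            truth, rng, prc_thetas, prc_delta, wedge_deltas, wedge_theta,
            seasonal_T, seasonal_tau)
    beta = truth.beta
    omega_L = truth.params.omega_L
    nrep = truth.n_replicates
    sigma = truth.noise_sigma

    def observe(clean):
        draws = rng.normal(loc=clean, scale=sigma, size=(nrep, clean.size))
        sem = draws.std(axis=0, ddof=1) / np.sqrt(nrep)
        # floor keeps zero-noise designs usable in the chi-squared fit
        return draws.mean(axis=0), np.maximum(sem, 1e-9)

    th = np.asarray(prc_thetas, dtype=float)
    clean = predict_prc(beta, th, prc_delta, omega_L)
    y, sem = observe(np.asarray(clean))
    prc = ObservationSet(
        kind="prc", y=y, sem=sem, theta_t=th,
        delta=np.full_like(th, prc_delta),
        side=np.where(th < beta.prc_breakpoint, "left", "right"),
        omega_L=omega_L, label="synthetic PRC",
    )
    de = np.asarray(wedge_deltas, dtype=float)
    clean = predict_wedge(beta, np.full_like(de, wedge_theta), de, omega_L)
    y, sem = observe(np.asarray(clean))
    wedge = ObservationSet(
        kind="wedge", y=y, sem=sem, theta_t=np.full_like(de, wedge_theta),
        delta=de, omega_L=omega_L, label="synthetic wedge",
    )
    TT, tt = np.meshgrid(np.asarray(seasonal_T, float),
                         np.asarray(seasonal_tau, float), indexing="ij")
    TT, tt = TT.ravel(), tt.ravel()
    clean = predict_seasonal(beta, tt, TT)
    y, sem = observe(np.asarray(clean))
    seasonal = ObservationSet(
        kind="seasonal", y=y, sem=sem, tau=tt, T=TT,
        omega_L=omega_L, label="synthetic seasonal",
    )
    return [prc, wedge, seasonal]


def _simulated_prc_wedge_seasonal(truth, rng, prc_thetas, prc_delta, wedge_deltas,
                                  wedge_theta, seasonal_T, seasonal_tau):
    """Full-simulation observation sets from an L/D step-response truth."""
    if truth.L is None or truth.D is None:
        raise ValueError("simulation-based generation needs L and D truths")
    params, L, D = truth.params, truth.L, truth.D
    omega_L = params.omega_L
    nrep, sigma = truth.n_replicates, truth.noise_sigma

    def observe(clean):
        clean = np.atleast_1d(np.asarray(clean, dtype=float))
        draws = rng.normal(loc=clean, scale=sigma, size=(nrep, clean.size))
        sem = draws.std(axis=0, ddof=1) / np.sqrt(nrep)
        return draws.mean(axis=0), np.maximum(sem, 1e-9)

    # dark-pulse responses: pulse start chosen so the pulse hits the target
    # phase exactly (theta0 = 0, so theta(s) = omega_L * s before the pulse)
    th = np.asarray(prc_thetas, dtype=float)
    starts = (th + 1.0) / omega_L  # one free-running cycle before the pulse
    starts = np.round(starts / 0.01) * 0.01  # snap to the simulation grid
    prc_tab = simulate_dark_pulse_prc(params, L, D, delta=prc_delta,
                                      pulse_starts=starts,
                                      t_total=float(np.ceil(starts.max() / 12.0) * 12 + 72))
    y, sem = observe(prc_tab["delta_tpk"])
    # a long dark pulse first engages D: the PRC's single breakpoint sits at
    # the dusk function's breakpoint (the dawn breakpoint is skipped by the
    # dusk jump when the two are anchored to entrained phases)
    breakpoint_guess = getattr(D, "breakpoint", 0.5)
    prc = ObservationSet(
        kind="prc", y=y, sem=sem, theta_t=prc_tab["theta_at_pulse"],
        delta=np.full_like(th, prc_delta),
        side=np.where(prc_tab["theta_at_pulse"] < breakpoint_guess, "left", "right"),
        omega_L=omega_L, label="simulated PRC",
    )
    de = np.asarray(wedge_deltas, dtype=float)
    start = round((wedge_theta + 1.0) / omega_L / 0.01) * 0.01
    clean = []
    for d in de:
        tab = simulate_dark_pulse_prc(params, L, D, delta=float(d),
                                      pulse_starts=[start],
                                      t_total=float(np.ceil((start + d) / 12.0) * 12 + 72))
        clean.append(tab["delta_tpk"][0])
    y, sem = observe(np.asarray(clean))
    wedge = ObservationSet(
        kind="wedge", y=y, sem=sem, theta_t=np.full_like(de, wedge_theta),
        delta=de, omega_L=omega_L, label="simulated wedge",
    )
    TT, tt = np.meshgrid(np.asarray(seasonal_T, float),
                         np.asarray(seasonal_tau, float), indexing="ij")
    TT, tt = TT.ravel(), tt.ravel()
    clean = []
    for T, tau in zip(TT, tt):
        sched = DrivingSchedule(T=float(T), tau=float(tau), n_cycles=12)
        res = iterate_diurnal_map(0.0, params, L, D, sched)
        clean.append(res.tpk_hours[-1])
    y, sem = observe(np.asarray(clean))
    seasonal = ObservationSet(
        kind="seasonal", y=y, sem=sem, tau=tt, T=TT,
        omega_L=omega_L, label="simulated seasonal",
    )
    return [prc, wedge, seasonal]
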