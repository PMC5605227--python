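"""File formats, pipeline configuration, and end-to-end pipeline drivers.

Interchange formats are deliberately plain: long-format CSV for time series
(columns ``time_h, series_id, value, light``), CSV node tables for step
functions (``phase_cycles, shift_cycles, kind``), CSV observation tables for
the global fit, and JSON for driving schedules.  All numeric fields
round-trip at full precision ('%.17g').

``run_pipeline`` binds the analysis modules into the four standard
pipelines (seasonal in vivo, seasonal in vitro, step response, global fit)
plus the geometry scan and synthetic-data generation, emitting result CSVs,
a machine-readable summary, and a run log with versions, seed, thresholds,
and the config hash.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import slope_over_grid
from .globalfit import ObservationSet, fit_beta_model
from .lineartheory import slope_m
from .phasemodel import DrivingSchedule, OscillatorParams
from .rhythms import (
    TimeSeriesTrajectory,
    fit_peaks_parabolic,
    fit_sinusoid,
    normalize_trajectory,
    regress_slope_with_errors,
    reject_outlier_fits,
)
from .stepresponse import StepResponseFunction, measure_step_responses
from .synth import GroundTruth, generate_reporter_timeseries, generate_step_experiment

__all__ = [
    "read_timeseries_csv", "write_timeseries_csv", "read_timeseries_workbook",
    "read_stepfun_csv", "write_stepfun_csv",
    "write_fits_csv", "read_observations_csv", "write_observations_csv",
    "schedule_to_json", "schedule_from_json",
    "PipelineConfig", "run_pipeline",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# time-series CSV


def read_timeseries_csv(path) -> list[TimeSeriesTrajectory]:
    """Read long-format rhythm data, one trajectory per series_id.

    Schema violations are reported with the (1-based, header-inclusive) line
    number of the first offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["time_h", "series_id", "value", "light"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["light"].isin([0, 1])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}: line {line}: light flag must be 0 or 1")
    notnum = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if notnum.any():
        line = int(df.index[notnum][0]) + 2
        raise ValueError(f"{path}: line {line}: non-numeric value")
    out = []
    for sid, grp in df.groupby("series_id", sort=True):
        grp = grp.sort_values("time_h")
        out.append(TimeSeriesTrajectory(
            times=grp["time_h"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
            light=grp["light"].to_numpy(dtype=int).astype(bool),
            series_id=str(sid),
        ))
    return out


def read_timeseries_workbook(path) -> list[TimeSeriesTrajectory]:
    """Import figure-source-style spreadsheets into trajectories.

    Each worksheet must have a ``time_h`` column, an optional ``light``
    column (0/1; all-light assumed when absent), and one column per recorded
    well/reaction; series are labeled ``<sheet>/<column>``.  This is the
    import path for tabular source-data workbooks; convert to long CSV with
    :func:`write_timeseries_csv` for the rest of the pipeline.
    """
    sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    out = []
    for sheet, df in sheets.items():
        if "time_h" not in df.columns:
            raise ValueError(f"{path}: sheet {sheet!r} lacks a time_h column")
        times = df["time_h"].to_numpy(dtype=float)
        if "light" in df.columns:
            bad = ~df["light"].isin([0, 1])
            if bad.any():
                line = int(df.index[bad][0]) + 2
                raise ValueError(
                    f"{path}: sheet {sheet!r} line {line}: light flag must be 0 or 1")
            light = df["light"].to_numpy(dtype=int).astype(bool)
        else:
            light = np.ones_like(times, dtype=bool)
        for col in df.columns:
            if col in ("time_h", "light"):
                continue
            out.append(TimeSeriesTrajectory(
                times=times.copy(),
                values=df[col].to_numpy(dtype=float),
                light=light.copy(),
                series_id=f"{sheet}/{col}",
            ))
    return out


def write_timeseries_csv(path, trajectories) -> None:
    frames = [
        pd.DataFrame({
            "time_h": t.times, "series_id": t.series_id, "value": t.values,
            "light": t.light.astype(int),
        })
        for t in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# step-function CSV


def read_stepfun_csv(path) -> dict[str, StepResponseFunction]:
    """Read step-response node tables; returns {kind: function}."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["phase_cycles", "shift_cycles", "kind"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for kind, grp in df.groupby("kind"):
        if kind not in ("dawn", "dusk"):
            line = int(grp.index[0]) + 2
            raise ValueError(f"{path}: line {line}: kind must be 'dawn' or 'dusk'")
        grp = grp.sort_values("phase_cycles")
        out[str(kind)] = StepResponseFunction(
            kind=str(kind),
            phases=grp["phase_cycles"].to_numpy(dtype=float),
            shifts=grp["shift_cycles"].to_numpy(dtype=float),
        )
    return out


def write_stepfun_csv(path, functions) -> None:
    frames = [
        pd.DataFrame({"phase_cycles": f.phases, "shift_cycles": f.shifts,
                      "kind": f.kind})
        for f in functions
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def write_fits_csv(path, fits) -> None:
    """Export sinusoid fits, one row per series."""
    pd.DataFrame([{
        "series_id": f.series_id, "A": f.amplitude, "T_h": f.period,
        "phi_rad": f.phase, "b": f.trend, "C": f.baseline,
        "sq_err": f.squared_error, "n": f.n_points,
    } for f in fits]).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# observations CSV


def write_observations_csv(path, observations) -> None:
    frames = []
    for o in observations:
        frames.append(pd.DataFrame({
            "kind": o.kind, "y": o.y, "sem": o.sem,
            "theta_t": o.theta_t if o.theta_t is not None else np.nan,
            "delta": o.delta if o.delta is not None else np.nan,
            "tau": o.tau if o.tau is not None else np.nan,
            "T": o.T if o.T is not None else np.nan,
            "side": o.side if o.side is not None else "",
            "omega_L": o.omega_L, "label": o.label,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def read_observations_csv(path) -> list[ObservationSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["kind", "y", "sem"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (kind, label), grp in df.groupby(["kind", "label"], dropna=False, sort=True):
        def col(name):
            if name not in grp or grp[name].isna().all():
                return None
            return grp[name].to_numpy()
        out.append(ObservationSet(
            kind=str(kind),
            y=grp["y"].to_numpy(dtype=float),
            sem=grp["sem"].to_numpy(dtype=float),
            theta_t=col("theta_t"), delta=col("delta"),
            tau=col("tau"), T=col("T"),
            side=None if col("side") is None else grp["side"].to_numpy(dtype=object),
            omega_L=float(grp["omega_L"].iloc[0]) if "omega_L" in grp else 1.0 / 24.0,
            label="" if pd.isna(label) else str(label),
        ))
    return out


# ---------------------------------------------------------------------------
# schedule JSON


def schedule_to_json(schedule: DrivingSchedule, path=None) -> str:
    doc = {
        "T_h": schedule.T, "tau_h": schedule.tau, "n_cycles": schedule.n_cycles,
        "release_time_h": schedule.release_time,
        "pulses": [{"start_h": s, "duration_h": d} for s, d in schedule.pulses],
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def schedule_from_json(source) -> DrivingSchedule:
    """Parse a schedule from a JSON string or file path."""
    p = Path(str(source))
    text = p.read_text() if p.exists() else str(source)
    doc = json.loads(text)
    known = {"T_h", "tau_h", "n_cycles", "release_time_h", "pulses"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown schedule keys: {sorted(unknown)}")
    return DrivingSchedule(
        T=float(doc["T_h"]), tau=float(doc["tau_h"]),
        n_cycles=int(doc.get("n_cycles", 0)),
        release_time=doc.get("release_time_h"),
        pulses=[(float(q["start_h"]), float(q["duration_h"]))
                for q in doc.get("pulses", [])],
    )


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    ``fitter`` selects the phase estimator for seasonal pipelines
    ("sinusoid" or "parabola"); thresholds and phase conventions are
    explicit so every run log records them.
    """

    seed: int = 0
    fitter: str = "sinusoid"
    timeseries_csv: Optional[str] = None
    observations_csv: Optional[str] = None
    schedule: dict = field(default_factory=dict)
    taus: list = field(default_factory=lambda: [8.0, 10.0, 12.0, 14.0, 16.0])
    T_day: float = 23.7
    T_night: float = 25.7
    l_true: float = 0.4
    d_true: float = 0.4
    noise_sigma: float = 0.1
    n_replicates: int = 4
    outlier_threshold: float = 10.0
    entrainment_sd_threshold: float = 0.01
    ec_variance_threshold: float = 0.01
    period_bounds: list = field(default_factory=lambda: [23.0, 25.0])
    invitro_period_bounds: list = field(default_factory=lambda: [20.0, 30.0])
    discard_after_lights_on: float = 2.5
    R_grid: list = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0])
    X_grid: list = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0])
    geometry_taus: list = field(default_factory=lambda: [6, 9, 12, 15, 18])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _seasonal_core(config, trajs_by_tau, schedules_by_tau):
    """Peak time vs day length and its regression slope."""
    rows = []
    for tau, trajs in trajs_by_tau.items():
        sched = schedules_by_tau[tau]
        release = sched.release_time
        peaks = []
        if config.fitter == "sinusoid":
            fits = []
            for traj in trajs:
                norm = normalize_trajectory(traj, config.discard_after_lights_on)
                keep = norm.mask & (norm.times >= release) & (
                    norm.times < release + 48.0)
                norm = TimeSeriesTrajectory(
                    times=norm.times, values=norm.values, light=norm.light,
                    series_id=norm.series_id, included=keep)
                fits.append(fit_sinusoid(norm, tuple(config.period_bounds)))
            fits, _ = reject_outlier_fits(fits, config.outlier_threshold)
            peaks = [f.peak_time_near(release + f.period / 2) - release for f in fits]
        elif config.fitter == "parabola":
            for traj in trajs:
                norm = normalize_trajectory(traj, config.discard_after_lights_on)
                keep = norm.mask & (norm.times >= release)
                norm = TimeSeriesTrajectory(
                    times=norm.times, values=norm.values, light=norm.light,
                    series_id=norm.series_id, included=keep)
                est = fit_peaks_parabolic(norm)
                if est.peak_times.size:
                    peaks.append(est.peak_times[0] - release)
        else:
            raise ValueError(f"unknown fitter {config.fitter!r}")
        if len(peaks) < 2:
            raise RuntimeError(f"seasonal pipeline: too few peaks at tau={tau}")
        rows.append({"tau_h": tau, "tpk_h": float(np.mean(peaks)),
                     "tpk_sd_h": float(np.std(peaks, ddof=1)), "n": len(peaks)})
    table = pd.DataFrame(rows)
    sd = np.maximum(table["tpk_sd_h"].to_numpy(), 1e-6)
    fit = regress_slope_with_errors(table["tau_h"], table["tpk_h"], sd)
    return table, fit


def run_pipeline(config: PipelineConfig, which: str, outdir) -> dict:
    """Run one named pipeline and write its report bundle to ``outdir``.

    Pipelines: ``seasonal_invivo`` (drive-and-release slope of peak time vs
    day length), ``seasonal_invitro`` (same on in-vitro-style data without
    masking), ``step_response`` (L/D extraction with linearized slopes),
    ``global_fit`` (beta model from an observations CSV or synthetic data),
    ``geometry_scan`` (m over an (R, X) grid), ``synth`` (write synthetic
    datasets).  Deterministic given config and seed.  Returns the summary
    dict (also written as summary.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    params = OscillatorParams(T_day=config.T_day, T_night=config.T_night)
    from .stepresponse import LinearStepParams  # local to avoid cycle at import
    L_true = LinearStepParams(kind="dawn", slope=config.l_true, anchor=1.0 / 12.0,
                              breakpoint=1.0 / 12.0 + 0.5)
    D_true = LinearStepParams(kind="dusk", slope=config.d_true, anchor=7.0 / 12.0,
                              breakpoint=7.0 / 12.0 - 0.5)
    truth = GroundTruth(params=params, L=L_true, D=D_true,
                        noise_sigma=config.noise_sigma,
                        n_replicates=config.n_replicates)
    summary: dict = {"pipeline": which, "seed": config.seed,
                     "config_hash": config.digest()}

    if which in ("seasonal_invivo", "seasonal_invitro"):
        if config.timeseries_csv:
            raise NotImplementedError(
                "externally supplied seasonal datasets need per-tau schedules; "
                "use the library API directly")
        if which == "seasonal_invitro":
            truth.masking_window = 0.0
            truth.mask_amplitude = 0.0
        trajs_by_tau, scheds = {}, {}
        for tau in config.taus:
            sched = DrivingSchedule(T=24.0, tau=float(tau), n_cycles=5)
            scheds[tau] = sched
            trajs_by_tau[tau] = generate_reporter_timeseries(
                truth, sched, rng, series_prefix=f"tau{tau:g}")
        table, fit = _seasonal_core(config, trajs_by_tau, scheds)
        table.to_csv(outdir / "peak_times.csv", index=False, float_format=_FLOAT_FMT)
        summary.update({"m": fit.slope, "m_sd": fit.slope_sd,
                        "intercept_h": fit.intercept,
                        "m_true": float(slope_m(config.l_true, config.d_true,
                                                params.freq_ratio))})

    elif which == "step_response":
        up = generate_step_experiment(truth, np.arange(2.0, 26.0, 2.0), "up", rng)
        down = generate_step_experiment(truth, np.arange(2.0, 26.0, 2.0), "down", rng)
        master = up
        master.members.extend(m for m in down.members if m.role == "stepped")
        meas = measure_step_responses(
            master, period_bounds=tuple(config.invitro_period_bounds))
        write_stepfun_csv(outdir / "step_functions.csv", [meas.L, meas.D])
        summary.update({
            "l": meas.L_lin.slope if meas.L_lin else None,
            "d": meas.D_lin.slope if meas.D_lin else None,
            "T_day_h": meas.T_day, "T_night_h": meas.T_night,
            "freq_ratio": meas.freq_ratio,
            "l_true": config.l_true, "d_true": config.d_true,
        })

    elif which == "global_fit":
        if config.observations_csv:
            observations = read_observations_csv(config.observations_csv)
        else:
            from .lineartheory import BetaModel
            from .synth import generate_prc_wedge_seasonal
            truth.beta = BetaModel(beta1=-1.31, beta2=1.79, c_prc_left=-22.11,
                                   c_prc_right=-36.98, c_wedge=-24.52,
                                   c_entrainment=39.8)
            observations = generate_prc_wedge_seasonal(truth, rng)
            write_observations_csv(outdir / "observations.csv", observations)
        result = fit_beta_model(observations)
        summary.update({
            "beta1": result.model.beta1, "beta2": result.model.beta2,
            "chi2": result.chi2, "chi2_nu": result.chi2_nu,
            "seasonal_slope": result.model.seasonal_slope,
            "ci95": {k: list(v) for k, v in result.ci95.items()},
        })

    elif which == "geometry_scan":
        scan = slope_over_grid(np.asarray(config.R_grid, float),
                               np.asarray(config.X_grid, float),
                               taus=np.asarray(config.geometry_taus, float))
        pd.DataFrame(scan["m"], index=scan["R"], columns=scan["X"]).to_csv(
            outdir / "slope_grid.csv", float_format=_FLOAT_FMT)
        summary.update({
            "n_entrained_cells": int(np.sum(~scan["mask"])),
            "m_min": float(np.nanmin(scan["m"])) if np.any(~scan["mask"]) else None,
            "m_max": float(np.nanmax(scan["m"])) if np.any(~scan["mask"]) else None,
        })

    elif which == "synth":
        sched = DrivingSchedule(T=24.0, tau=12.0, n_cycles=5)
        trajs = generate_reporter_timeseries(truth, sched, rng)
        write_timeseries_csv(outdir / "timeseries.csv", trajs)
        schedule_to_json(sched, outdir / "schedule.json")
        summary.update({"n_series": len(trajs), "truth": truth.to_dict()})

    else:
        raise ValueError(f"unknown pipeline {which!r}")

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "thresholds": {
            "outlier": config.outlier_threshold,
            "entrainment_sd_cycles": config.entrainment_sd_threshold,
            "ec_variance_cycles2": config.ec_variance_threshold,
        },
        "phase_convention": "theta_hat in cycles; 0 = phosphorylation trough, "
                            "0.5 = peak; CT hours = 24 * theta_hat",
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return summary
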