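"""Global chi-squared fit of the two-slope linear-response (beta) model.

Phase-resetting (PRC), wedge, and seasonal-entrainment measurements are fit
simultaneously: two shared parameters (beta1, beta2) fix the slopes of all
curves, and four intercepts (PRC left/right of the breakpoint, wedge,
entrainment) absorb the constant terms, for six parameters in total.  The
cost is ``chi2 = sum_i ((y_i - yfit_i)/sigma_i)^2`` with sigma_i the
standard error of each averaged measurement.  For fixed (beta1, beta2) the
intercepts enter linearly and are profiled out, so the optimization is a 2-D
nonlinear least-squares problem; confidence intervals come from the local
curvature of the cost at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy import optimize

from .lineartheory import BetaModel

__all__ = ["ObservationSet", "GlobalFitResult", "fit_beta_model", "chi_squared",
           "scan_prc_breakpoint"]

_GROUPS = ("prc_left", "prc_right", "wedge", "entrainment")


@dataclass
class ObservationSet:
    """Averaged measurements of one kind with their standard errors.

    kind "prc": predictors ``theta_t`` (cycles) and ``delta`` (hours), with a
    per-point ``side`` label ("left"/"right" of the PRC breakpoint) and the
    light frequency ``omega_L`` (cycles/h); response is the peak-time shift.
    kind "wedge": same predictors, single intercept.  kind "seasonal":
    predictors ``tau`` and ``T`` (hours); response is the entrained peak
    time.
    """

    kind: str
    y: np.ndarray
    sem: np.ndarray
    theta_t: Optional[np.ndarray] = None
    delta: Optional[np.ndarray] = None
    tau: Optional[np.ndarray] = None
    T: Optional[np.ndarray] = None
    side: Optional[np.ndarray] = None
    omega_L: float = 1.0 / 24.0
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("prc", "wedge", "seasonal"):
            raise ValueError(f"unknown observation kind {self.kind!r}")
        self.y = np.asarray(self.y, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if np.any(self.sem <= 0):
            raise ValueError("standard errors must be positive")
        need = {"prc": ("theta_t", "delta", "side"),
                "wedge": ("theta_t", "delta"),
                "seasonal": ("tau", "T")}[self.kind]
        for name in need:
            val = getattr(self, name)
            if val is None:
                raise ValueError(f"{self.kind} observations need {name}")
            arr = np.asarray(val)
            if arr.shape != self.y.shape:
                raise ValueError(f"{name} length differs from y")
            setattr(self, name, arr if name == "side" else arr.astype(float))

    def __len__(self) -> int:
        return self.y.size

    def base_prediction(self, beta1: float, beta2: float) -> np.ndarray:
        """Model prediction without the intercept term."""
        if self.kind == "seasonal":
            return self.tau * (1.0 - beta1 - beta2) + self.T * beta1
        return (self.theta_t / (self.omega_L * beta2)
                + self.delta * (1.0 + beta1 / beta2))

    def groups(self) -> np.ndarray:
        """Intercept-group label per observation."""
        if self.kind == "seasonal":
            return np.full(len(self), "entrainment", dtype=object)
        if self.kind == "wedge":
            return np.full(len(self), "wedge", dtype=object)
        return np.array(["prc_left" if s == "left" else "prc_right"
                         for s in self.side], dtype=object)


@dataclass
class GlobalFitResult:
    """Best-fit beta model, confidence intervals, and goodness of fit."""

    model: BetaModel
    ci95: dict  # parameter name -> (lo, hi)
    chi2: float
    chi2_nu: Optional[float]
    n_obs: int
    n_params: int = 6


def _stack(observations: Sequence[ObservationSet]):
    y = np.concatenate([o.y for o in observations])
    sem = np.concatenate([o.sem for o in observations])
    groups = np.concatenate([o.groups() for o in observations])
    return y, sem, groups


def _profiled_residuals(beta1, beta2, observations, y, sem, groups):
    base = np.concatenate([o.base_prediction(beta1, beta2) for o in observations])
    resid = (y - base) / sem
    pred = base.copy()
    for g in _GROUPS:
        sel = groups == g
        if np.any(sel):
            w = 1.0 / sem[sel] ** 2
            c = float(np.sum(w * (y[sel] - base[sel])) / np.sum(w))
            pred[sel] = base[sel] + c
    return (y - pred) / sem, pred


def chi_squared(
    observations: Sequence[ObservationSet], model: BetaModel
) -> tuple[float, Optional[float]]:
    """Evaluate chi2 and reduced chi2 for fully specified parameters."""
    intercepts = {"prc_left": model.c_prc_left, "prc_right": model.c_prc_right,
                  "wedge": model.c_wedge, "entrainment": model.c_entrainment}
    y, sem, groups = _stack(observations)
    base = np.concatenate(
        [o.base_prediction(model.beta1, model.beta2) for o in observations])
    pred = base + np.array([intercepts[g] for g in groups])
    chi2 = float(np.sum(((y - pred) / sem) ** 2))
    n = y.size
    if n <= 6:
        warnings.warn("N <= 6: reduced chi-squared undefined")
        return chi2, None
    return chi2, chi2 / (n - 6)


def _full_residuals(params, observations, y, sem, groups):
    beta1, beta2 = params[0], params[1]
    intercepts = dict(zip(_GROUPS, params[2:]))
    base = np.concatenate([o.base_prediction(beta1, beta2) for o in observations])
    pred = base + np.array([intercepts[g] for g in groups])
    return (y - pred) / sem


def fit_beta_model(
    observations: Sequence[ObservationSet],
    n_starts: int = 10,
    seed: int = 0,
) -> GlobalFitResult:
    """Fit (beta1, beta2) plus four intercepts by chi-squared minimization.

    All three dataset kinds should be present; fitting a subset is allowed
    with a warning (some intercepts are then unidentified and reported as
    NaN).  Rank deficiency in the identified directions (e.g. seasonal data
    at a single day length) raises with the offending direction named.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("no observations")
    kinds = {o.kind for o in observations}
    if kinds != {"prc", "wedge", "seasonal"}:
        warnings.warn(f"global fit without all three dataset kinds (got {sorted(kinds)})")
    y, sem, groups = _stack(observations)
    present = [g for g in _GROUPS if np.any(groups == g)]

    rng = np.random.default_rng(seed)
    starts = [(-1.0, 1.5)] + [
        (rng.uniform(-3.0, 1.0), rng.uniform(0.3, 3.0)) for _ in range(n_starts - 1)
    ]
    best = None
    for b1, b2 in starts:
        try:
            res = optimize.least_squares(
                lambda p: _profiled_residuals(p[0], p[1], observations, y, sem,
                                              groups)[0],
                x0=[b1, b2],
                bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("beta-model optimization failed from every start")
    beta1, beta2 = best.x
    # recover profiled intercepts
    base = np.concatenate([o.base_prediction(beta1, beta2) for o in observations])
    intercepts = {}
    for g in _GROUPS:
        sel = groups == g
        if np.any(sel):
            w = 1.0 / sem[sel] ** 2
            intercepts[g] = float(np.sum(w * (y[sel] - base[sel])) / np.sum(w))
        else:
            intercepts[g] = float("nan")

    full = np.array([beta1, beta2] + [intercepts[g] for g in _GROUPS])
    free = [0, 1] + [2 + i for i, g in enumerate(_GROUPS) if g in present]
    names = ["beta1", "beta2", "c_prc_left", "c_prc_right", "c_wedge",
             "c_entrainment"]

    def resid_free(p_free):
        p = full.copy()
        p[free] = p_free
        return _full_residuals(p, observations, y, sem, groups)

    eps = 1e-6
    r0 = resid_free(full[free])
    J = np.empty((r0.size, len(free)))
    for k in range(len(free)):
        p = full[free].copy()
        h = eps * max(1.0, abs(p[k]))
        p[k] += h
        J[:, k] = (resid_free(p) - r0) / h
    JTJ = J.T @ J
    u, s, _ = np.linalg.svd(JTJ)
    if s[-1] < 1e-10 * s[0]:
        worst = int(np.argmax(np.abs(u[:, -1])))
        raise ValueError(
            f"rank-deficient design: parameter {names[free[worst]]!r} is "
            "unconstrained by the supplied observations"
        )
    cov = np.linalg.inv(JTJ)
    sd = np.sqrt(np.diag(cov))
    ci95 = {}
    for k, idx in enumerate(free):
        ci95[names[idx]] = (float(full[idx] - 1.96 * sd[k]),
                            float(full[idx] + 1.96 * sd[k]))

    model = BetaModel(
        beta1=float(beta1), beta2=float(beta2),
        c_prc_left=intercepts["prc_left"], c_prc_right=intercepts["prc_right"],
        c_wedge=intercepts["wedge"], c_entrainment=intercepts["entrainment"],
    )
    chi2, chi2_nu = chi_squared(observations, model)
    return GlobalFitResult(model=model, ci95=ci95, chi2=chi2, chi2_nu=chi2_nu,
                           n_obs=y.size)


def scan_prc_breakpoint(
    observations: Sequence[ObservationSet],
    candidates,
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[float, GlobalFitResult]:
    """Optimize the PRC breakpoint by a 1-D chi-squared scan (extension).

    The conventional workflow fixes the breakpoint from inspection of the
    PRC; this helper instead re-labels the PRC sides for each candidate
    breakpoint phase, refits the full model, and returns the candidate with
    the lowest chi-squared together with its fit.
    """
    best = None
    for bp in candidates:
        relabeled = []
        for o in observations:
            if o.kind == "prc":
                o = ObservationSet(
                    kind="prc", y=o.y, sem=o.sem, theta_t=o.theta_t,
                    delta=o.delta,
                    side=np.where(o.theta_t < bp, "left", "right"),
                    omega_L=o.omega_L, label=o.label)
            relabeled.append(o)
        sides = {s for o in relabeled if o.kind == "prc" for s in o.side}
        if len(sides) < 2:
            continue  # breakpoint outside the sampled phases
        res = fit_beta_model(relabeled, n_starts=n_starts, seed=seed)
        if best is None or res.chi2 < best[1].chi2:
            best = (float(bp), res)
    if best is None:
        raise ValueError("no candidate breakpoint splits the PRC phases")
    best[1].model.prc_breakpoint = best[0]
    return best
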