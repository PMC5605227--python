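"""Closed-form entrainment theory for linear step-response functions.

With linear dawn/dusk responses ``L(theta) = -l*(theta - theta_L)`` and
``D(theta) = -d*(theta - theta_D)``, the composed dawn-to-dawn map is affine
with contraction factor (1-l)(1-d), so the entrained phase has a closed
form, and the peak time after dawn is linear in day length, t_pk = m*tau + C.

The slope is ``m = d*(1-l)/(d+l-l*d)`` when the free-running frequency is
the same in light and dark, and in general (frequency ratio
rho = omega_D/omega_L)::

    m(l, d, rho) = 1 - (1 - (1-l)*rho) / (d + l - l*d)
                 = (1-l) * (rho - 1 + d) / (d + l - l*d),

which is derived here from the affine fixed point (differentiate the
entrained post-dawn phase with respect to tau and convert to peak time) and
validated against map simulations in the test suite.  The module also
implements the two-parameter (beta1, beta2) linear-response model that ties
phase-resetting, wedge, and seasonal-entrainment measurements together, and
the daytime resource-allocation bias computation.

The (l, d) and (beta1, beta2) parameterizations are kept distinct; no
conversion between them is asserted by the library.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from ._phase import wrap_cycles
from .phasemodel import OscillatorParams
from .stepresponse import LinearStepParams

__all__ = [
    "LinearEntrainmentModel",
    "FixedPoint",
    "BetaModel",
    "AllocationProfile",
    "slope_m",
    "entrained_fixed_point",
    "predict_prc",
    "predict_wedge",
    "predict_seasonal",
    "allocation_bias",
]


def slope_m(l, d, freq_ratio=1.0):
    """Slope of entrained peak time vs day length for linear L and D.

    ``freq_ratio`` is omega_D/omega_L = T_day/T_night.  At ratio 1 this is
    d(1-l)/(d+l-ld): full dawn resetting (l=1) gives m=0 (dawn tracking),
    pure dusk resetting (l=0, d=1) gives m=1 (dusk tracking).  Broadcasts
    over array inputs.
    """
    l = np.asarray(l, dtype=float)
    d = np.asarray(d, dtype=float)
    denom = d + l - l * d
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("degenerate parameters: d + l - l*d = 0 (no unique fixed point)")
    out = 1.0 - (1.0 - (1.0 - l) * freq_ratio) / denom
    return out if out.ndim else float(out)


@dataclass
class LinearEntrainmentModel:
    """Linear L/D slopes and anchors plus light/dark frequencies.

    Angles in cycles; frequencies in cycles/hour.
    """

    l: float
    d: float
    theta_L: float
    theta_D: float
    omega_L: float
    omega_D: float

    @classmethod
    def from_params(
        cls,
        L: LinearStepParams,
        D: LinearStepParams,
        params: OscillatorParams,
    ) -> "LinearEntrainmentModel":
        return cls(l=L.slope, d=D.slope, theta_L=L.anchor, theta_D=D.anchor,
                   omega_L=params.omega_L, omega_D=params.omega_D)

    @property
    def contraction(self) -> float:
        """Per-cycle dawn-phase error contraction factor (1-l)(1-d)."""
        return (1.0 - self.l) * (1.0 - self.d)

    @property
    def freq_ratio(self) -> float:
        return self.omega_D / self.omega_L

    @property
    def m(self) -> float:
        return slope_m(self.l, self.d, self.freq_ratio)

    def step_functions(self) -> tuple[LinearStepParams, LinearStepParams]:
        """Breakpointed linear L and D with breakpoints opposite the anchors."""
        L = LinearStepParams(kind="dawn", slope=self.l, anchor=self.theta_L,
                             breakpoint=wrap_cycles(self.theta_L + 0.5))
        D = LinearStepParams(kind="dusk", slope=self.d, anchor=self.theta_D,
                             breakpoint=wrap_cycles(self.theta_D + 0.5))
        return L, D


@dataclass
class FixedPoint:
    """Entrained fixed point of the affine dawn-to-dawn map."""

    dawn_phase_pre: float  # phase at dawn before the L shift, cycles in [0,1)
    dawn_phase_post: float  # phase immediately after the L shift
    dusk_phase: float  # phase at dusk before the D shift
    contraction: float
    tpk_hours: float  # time after dawn to reach phase 0.5


def entrained_fixed_point(
    model: LinearEntrainmentModel, T: float = 24.0, tau: float = 12.0
) -> FixedPoint:
    """Closed-form entrained phase for the linear dawn/dusk map.

    The pre-shift dawn phase obeys ``theta* = B + c*theta* (mod 1)`` with
    ``c = (1-l)(1-d)`` and ``B = (1-d)(l*theta_L + omega_L*tau) + d*theta_D
    + omega_D*(T-tau)``; candidates ``(B-k)/(1-c)`` over integer windings k
    are screened against one iteration of the actual wrapped map (with the
    breakpointed step functions) to select the fixed point on the principal
    branch.

    Raises for marginal stability (|contraction| >= 1, e.g. l = d = 0).
    """
    l, d = model.l, model.d
    c = model.contraction
    if abs(c) >= 1.0:
        raise ValueError(
            f"marginal or unstable map: |(1-l)(1-d)| = {abs(c):.3f} >= 1; "
            "no entrained fixed point"
        )
    B = ((1.0 - d) * (l * model.theta_L + model.omega_L * tau)
         + d * model.theta_D + model.omega_D * (T - tau))
    L, D = model.step_functions()

    def one_cycle(theta):
        th = theta + float(L(theta))
        th_dusk = th + model.omega_L * tau
        return th_dusk + float(D(wrap_cycles(th_dusk))) + model.omega_D * (T - tau)

    k_center = int(np.floor(B))
    for k in range(k_center - 2, k_center + 4):
        theta = (B - k) / (1.0 - c)
        if not (0.0 <= theta < 1.0):
            continue
        if abs(wrap_cycles(one_cycle(theta) - theta + 0.5) - 0.5) < 1e-9:
            post = theta + float(L(theta))
            dusk = post + model.omega_L * tau
            tpk = wrap_cycles(0.5 - wrap_cycles(post)) / model.omega_L
            return FixedPoint(
                dawn_phase_pre=float(theta),
                dawn_phase_post=float(wrap_cycles(post)),
                dusk_phase=float(wrap_cycles(dusk)),
                contraction=float(c),
                tpk_hours=float(tpk),
            )
    raise ValueError(
        "no fixed point on the principal branch (entrained phase would cross "
        "a breakpoint); iterate the map instead"
    )


# ---------------------------------------------------------------------------
# beta model


@dataclass
class BetaModel:
    """Two-slope linear-response model for PRC, wedge, and seasonal data.

    ``delta_tpk = theta_t/(omega_L*beta2) + delta*(1 + beta1/beta2) + C1``
    for phase-resetting (dark pulse of duration delta starting at clock
    phase theta_t, cycles), with separate intercepts left and right of the
    PRC breakpoint and for the wedge protocol; and
    ``tpk = tau*(1 - beta1 - beta2) + T*beta1 + C2`` for entrainment to
    light-dark cycles of period T and day length tau (hours).
    """

    beta1: float
    beta2: float
    c_prc_left: float = 0.0
    c_prc_right: float = 0.0
    c_wedge: float = 0.0
    c_entrainment: float = 0.0
    prc_breakpoint: float = 0.5  # cycles

    def __post_init__(self):
        if self.beta2 == 0:
            raise ValueError("beta2 must be nonzero")

    @property
    def seasonal_slope(self) -> float:
        """Slope of entrained peak time vs day length, 1 - beta1 - beta2."""
        return 1.0 - self.beta1 - self.beta2

    @property
    def wedge_slope(self) -> float:
        """Slope of the peak-time shift vs pulse duration, 1 + beta1/beta2."""
        return 1.0 + self.beta1 / self.beta2


def predict_prc(beta: BetaModel, theta_t, delta, omega_L: float):
    """Peak-time shift for a dark pulse: intercept chosen by breakpoint side.

    ``theta_t`` exactly at the breakpoint is ambiguous and raises.
    """
    theta_t = np.asarray(theta_t, dtype=float)
    if np.any(theta_t == beta.prc_breakpoint):
        raise ValueError("theta_t exactly at the PRC breakpoint: side indeterminate")
    c = np.where(theta_t < beta.prc_breakpoint, beta.c_prc_left, beta.c_prc_right)
    out = theta_t / (omega_L * beta.beta2) + np.asarray(delta) * beta.wedge_slope + c
    return out if out.ndim else float(out)


def predict_wedge(beta: BetaModel, theta_t, delta, omega_L: float):
    """Peak-time shift vs pulse duration at a (near-)fixed clock phase."""
    out = (np.asarray(theta_t, dtype=float) / (omega_L * beta.beta2)
           + np.asarray(delta, dtype=float) * beta.wedge_slope + beta.c_wedge)
    return out if out.ndim else float(out)


def predict_seasonal(beta: BetaModel, tau, T):
    """Entrained peak time (hours after dawn) vs day length and period."""
    out = (np.asarray(tau, dtype=float) * beta.seasonal_slope
           + np.asarray(T, dtype=float) * beta.beta1 + beta.c_entrainment)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# daytime resource allocation


@dataclass
class AllocationProfile:
    """Sinusoidal dawn/dusk transcription waveforms for allocation estimates.

    Each program is a 24 h sinusoid, rectified at zero, peaking
    ``dawn_peak_h``/``dusk_peak_h`` hours after dawn under the reference
    day length (``reference_tau``, the 12:12 synchronization condition).  A
    clock tracking day length with slope ``m`` shifts the whole program by
    ``m*(tau - reference_tau)`` hours relative to dawn.
    """

    dawn_peak_h: float = 2.0
    dusk_peak_h: float = 14.0
    dawn_amplitude: float = 1.0
    dusk_amplitude: float = 1.0
    reference_tau: float = 12.0

    def waveform(self, gene: str, t, m: float, tau: float) -> np.ndarray:
        peak = self.dawn_peak_h if gene == "dawn" else self.dusk_peak_h
        amp = self.dawn_amplitude if gene == "dawn" else self.dusk_amplitude
        shift = m * (tau - self.reference_tau)
        t = np.asarray(t, dtype=float)
        w = amp * np.cos(2.0 * np.pi * (t - peak - shift) / 24.0)
        return np.maximum(w, 0.0)


def allocation_bias(
    profile: AllocationProfile, m: float, tau: float, n_quad: int = 2001
) -> float:
    """Bias of daytime expression toward the dawn program.

    Integrates the rectified dawn and dusk waveforms over the daylight hours
    [0, tau] (with the circadian program phase-shifted according to the
    entrainment slope ``m``) and returns
    ``(I_dawn - I_dusk) / (I_dawn + I_dusk)``, in [-1, 1].
    """
    t = np.linspace(0.0, tau, n_quad)
    i_dawn = np.trapezoid(profile.waveform("dawn", t, m, tau), t)
    i_dusk = np.trapezoid(profile.waveform("dusk", t, m, tau), t)
    total = i_dawn + i_dusk
    if total == 0:
        raise ValueError("both programs integrate to zero over the day window")
    return float((i_dawn - i_dusk) / total)
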