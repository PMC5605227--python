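"""Phase arithmetic and circular statistics shared across modules.

Phases are expressed in cycles (1 cycle = 2*pi rad = one full revolution)
unless a function name says otherwise.  The wrapped representative of a
phase lives in [0, 1); phase *differences* are wrapped to (-0.5, 0.5] so
that the winding-0 convention (no shift ever exceeds one cycle) has an
unambiguous branch.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_cycles(x):
    """Wrap phase(s) in cycles to [0, 1)."""
    x = np.asarray(x, dtype=float)
    out = x - np.floor(x)
    return out if out.ndim else float(out)


def wrap_half_cycles(x):
    """Wrap phase difference(s) in cycles to (-0.5, 0.5]."""
    x = np.asarray(x, dtype=float)
    out = x - np.ceil(x - 0.5)
    return out if out.ndim else float(out)


def wrap_interval(x, period):
    """Wrap difference(s) to (-period/2, period/2] (e.g. peak times in hours)."""
    x = np.asarray(x, dtype=float)
    out = x - period * np.ceil(x / period - 0.5)
    return out if out.ndim else float(out)


def wrap_pi(x):
    """Wrap angle difference(s) in radians to (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    out = x - TWO_PI * np.ceil(x / TWO_PI - 0.5)
    return out if out.ndim else float(out)


def circular_mean_cycles(phases) -> float:
    """Circular mean of phases in cycles, returned in [0, 1)."""
    ang = TWO_PI * np.asarray(phases, dtype=float)
    mean = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return float(wrap_cycles(mean / TWO_PI))


def _centered_deviations(phases) -> np.ndarray:
    mu = circular_mean_cycles(phases)
    return wrap_half_cycles(np.asarray(phases, dtype=float) - mu)


def circular_sd_cycles(phases, ddof: int = 1) -> float:
    """Sample standard deviation of phases about their circular mean.

    Deviations are wrapped to (-0.5, 0.5] before the ordinary (ddof-corrected)
    standard deviation is taken, so sequences straddling the 0/1 wrap are
    handled correctly while tightly clustered sequences reproduce the naive
    standard deviation.
    """
    dev = _centered_deviations(phases)
    return float(np.std(dev, ddof=ddof))


def circular_var_cycles(phases, ddof: int = 1) -> float:
    """Sample variance analog of :func:`circular_sd_cycles` (cycles^2)."""
    dev = _centered_deviations(phases)
    return float(np.var(dev, ddof=ddof))
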