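"""Closed-form linear theory: entrained fixed point and the slope m(l, d).

Evaluates the entrained-phase slope for the measured step-response slopes,
propagates their uncertainty, verifies the closed-form fixed point against
the iterated map, and prints the daytime resource-allocation bias a
midday-tracking clock maintains across day lengths.
"""

import numpy as np

from cyanoclock.lineartheory import (
    AllocationProfile, LinearEntrainmentModel, allocation_bias,
    entrained_fixed_point, slope_m,
)
from cyanoclock.phasemodel import DrivingSchedule, OscillatorParams, iterate_diurnal_map

m_point = slope_m(0.34, 0.38, 0.93)
rng = np.random.default_rng(0)
m_dist = slope_m(rng.normal(0.34, 0.03, 1000), rng.normal(0.38, 0.05, 1000), 0.93)
print(f"m(0.34, 0.38, ratio 0.93) = {m_point:.3f}")
print(f"propagated over slope uncertainty: m = {m_dist.mean():.2f} "
      f"+/- {m_dist.std():.2f}")

model = LinearEntrainmentModel(l=0.34, d=0.38, theta_L=1 / 12, theta_D=7 / 12,
                               omega_L=1 / 23.7, omega_D=1 / 25.7)
fp = entrained_fixed_point(model, T=24.0, tau=12.0)
params = OscillatorParams(23.7, 25.7)
L, D = model.step_functions()
res = iterate_diurnal_map(0.3, params, L, D, DrivingSchedule(24.0, 12.0, 200))
print(f"\nfixed point (dawn, pre-shift): {fp.dawn_phase_pre:.6f} cycles;"
      f" map limit: {res.dawn_phases_pre[-1]:.6f}")
print(f"per-cycle contraction (1-l)(1-d) = {fp.contraction:.3f};"
      f" peak {fp.tpk_hours:.2f} h after dawn")

prof = AllocationProfile(dawn_peak_h=2.0, dusk_peak_h=14.0)
print("\nallocation bias (dawn vs dusk program share of daylight expression):")
for tau in (8.0, 12.0, 16.0):
    b_mid = allocation_bias(prof, 0.5, tau)
    b_dawn = allocation_bias(prof, 0.0, tau)
    print(f"  tau = {tau:4.0f} h: midday-tracking {b_mid:+.2f},"
          f" dawn-tracking {b_dawn:+.2f}")
print("midday tracking keeps the bias flatter across seasons than dawn tracking.")
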