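# cyanoclock

Modeling and analysis of how the cyanobacterial circadian clock entrains to
light-dark cycles — in particular, how the phase of the clock tracks the
middle of the day as day length changes with the seasons.

The package is written for chronobiologists and systems biologists who work
with driven oscillator data: bioluminescence reporter rhythms from cells in
programmable light-dark schedules, fluorescence-polarization or KaiC
phosphorylation rhythms from the reconstituted KaiABC oscillator, and
phase-response experiments (dark pulses, step perturbations).

## The model

The clock is reduced to a phase variable θ̂ (in cycles; θ̂ = 0 at the trough
of the KaiC phosphorylation rhythm, θ̂ = 0.5 at its peak).  Phase advances at
rate ω_L = 1/T_day in the light and ω_D = 1/T_night in the dark, and shifts
instantaneously at environmental transitions by the **step-response
functions** L(θ) (dawn) and D(θ) (dusk):

    θ̂_dawn(n)  =  θ̂_dusk(n−1) + D(θ̂_dusk mod 1) + (T−τ)/T_night
    θ̂_dusk(n)  =  θ̂_dawn(n) + L(θ̂_dawn mod 1) + τ/T_day

for a driving cycle of period T and day length τ.  When L and D are linear
over the phases used during entrainment, L(θ) = −l·(θ−θ_L) and
D(θ) = −d·(θ−θ_D), the dawn-to-dawn map is an affine contraction with factor
(1−l)(1−d), the entrained phase has a closed form, and the peak time after
dawn is linear in day length, t_pk = m·τ + C, with

    m(l, d) = 1 − [1 − (1−l)·(ω_D/ω_L)] / (d + l − l·d),

reducing to d(1−l)/(d+l−ld) when the light and dark frequencies are equal.
The measured slopes l ≈ 0.34, d ≈ 0.38 and frequency ratio ω_D/ω_L ≈ 0.93
give m ≈ 0.35 — the clock keeps a fixed relation to midday.  The same two
slopes also fix the responses to dark pulses: the β-model
(β₂ = shared PRC slope scale, β₁ the period-coupling term) predicts
Δt_pk = θ̂_t/(ω_L β₂) + δ(1 + β₁/β₂) + C₁ for a pulse of duration δ at
phase θ̂_t, and t_pk = τ(1−β₁−β₂) + Tβ₁ + C₂ for seasonal entrainment.
Finally, a geometric model — a unit daytime limit cycle and a night cycle of
radius R offset by X, with transitions as radial jumps — shows when such
near-linear step responses arise: midday tracking requires R ≈ X.

## Modules

| module          | what it does |
|-----------------|--------------|
| `rhythms`       | normalization, sinusoid/parabola phase estimation, outlier rejection, Kendall-τ waveform comparison, dark-pulse shifts, weighted regression |
| `stepresponse`  | L/D measurement from step experiments, periodic interpolants, linearization, bootstrap uncertainty |
| `phasemodel`    | iterated dawn/dusk map, continuous-time simulation, entrainment detection, PRC and driving-period scans |
| `lineartheory`  | closed-form fixed point, m(l,d), β-model predictions, allocation bias |
| `geometry`      | day/night limit-cycle model, derived L/D, (R,X) sweeps, relaxed-assumption dynamics |
| `globalfit`     | simultaneous χ² fit of the β-model to PRC + wedge + seasonal data |
| `synth`         | seeded ground-truth generators for every dataset shape |
| `io`            | CSV/JSON/workbook formats, pipeline drivers, thin CLI (`cyanoclock`) |

## Worked example

```python
import numpy as np
from cyanoclock.lineartheory import slope_m
from cyanoclock.phasemodel import DrivingSchedule, OscillatorParams, iterate_diurnal_map
from cyanoclock.stepresponse import LinearStepParams

params = OscillatorParams(T_day=23.7, T_night=25.7)
L = LinearStepParams(kind="dawn", slope=0.34, anchor=1/12, breakpoint=1/12 + 0.5)
D = LinearStepParams(kind="dusk", slope=0.38, anchor=7/12, breakpoint=7/12 - 0.5)

taus = np.arange(6.0, 18.1, 2.0)
tpk = [iterate_diurnal_map(0.0, params, L, D,
                           DrivingSchedule(24.0, t, 10)).tpk_hours[-1]
       for t in taus]
print(np.polyfit(taus, tpk, 1)[0])   # 0.337
print(slope_m(0.34, 0.38, 23.7/25.7))  # 0.3466
```

The simulated slope of peak time versus day length (0.337) agrees with the
closed-form m(l, d) at the simulated frequency ratio (0.347 at the rounded
ratio 0.93); both mean the phosphorylation peak moves about 20 minutes later
per extra hour of daylight — midday-range tracking.  The `examples/`
directory has one narrative script per capability (rhythm fitting, step
responses, entrainment simulation, linear theory, geometry, global fit),
each printing the numbers it computes and what they mean.

A thin CLI covers the simulation use case:

```sh
cyanoclock simulate schedule.json stepfunctions.csv --t-day 23.7 --t-night 25.7
cyanoclock pipeline step_response --outdir out/
```

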