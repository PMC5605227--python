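# Methods

## Model and assumptions

The package treats the circadian oscillator as a single phase variable.
Three ingredients define the driven dynamics: a free-running period in the
light (T_day, default 23.7 h), a free-running period in the dark (T_night,
default 25.7 h), and two 1-cycle-periodic step-response functions — L(θ)
for dark-to-light transitions and D(θ) for light-to-dark transitions —
giving the instantaneous phase shift as a function of the clock phase at
which the transition occurs.  The underlying assumption is fast relaxation:
after an environmental switch the oscillator collapses quickly onto the
limit cycle of the new condition, so the whole response can be summarized
by a phase shift.  Shifts are assumed never to exceed one cycle (winding
number 0), and phase differences are reported on the branch (−0.5, 0.5]
cycles.

Phase convention: θ̂ in cycles with θ̂ = 0 at the trough of the KaiC
phosphorylation rhythm and θ̂ = 0.5 at its peak; circadian time is
CT = 24·θ̂ h regardless of the condition-specific periods.  Internally phase
accumulates unwrapped; step functions are evaluated at the wrapped phase
and wrapping is applied only at evaluation and reporting, which removes
branch ambiguity from the iterated map.

Two drivers implement the same dynamics: the iterated dawn/dusk map (one
algebraic update per transition) and an explicit continuous-time stepper
(default dt = 0.01 h).  Because phase velocity is piecewise constant, the
two agree exactly (tested to 1e−10) for pulse-free schedules; the
continuous path exists for protocols with dark pulses inside constant
light, which are realized as a dusk step at pulse start and a dawn step at
pulse end.  Transitions must land on the time grid; off-grid transitions
raise instead of being rounded.

## Estimation pipeline

Reporter trajectories are z-scored over the retained samples after masking:
all dark samples, plus the first 2.5 h after every dark-to-light transition
(luciferase masking transients), are excluded.  Sinusoids
A·sin(2πt/T − φ) + bt + C are fit by variable projection: for fixed period
all remaining parameters are linear, so the fit is an exact linear solve
inside a 1-D bounded search over the period (grid plus local refinement).
This finds the global optimum of the stated least-squares cost without
multi-start heuristics.  The period is constrained to 23–25 h for in vivo
free-run fits, shared across replicate reactions for in vitro fits, or
fixed at the driving period where the protocol imposes one.  Local
parabolic peak fitting (6 h windows around local maxima of a 3-sample
moving median, minimum separation 12 h) provides the complementary
peak-time estimator for asymmetric waveforms; both estimators are exposed
and pipelines select one explicitly.  Fits with squared error above 10
(normalized units) are rejected as outliers, the threshold being the
conventional plate-assay cutoff.

Step-response measurement evaluates the control and perturbed fits at the
step time: the control gives the phase at which the step occurred, the
difference of apparent phases gives the shift.  Evaluating both at the same
instant disentangles the instantaneous shift from the period change across
the step.  Because the raw fit-phase formula θ = t/T − φ/2π places the
fitted sinusoid's peak at 0.25 cycles while the clock convention puts the
reporter peak at 0.5, measured step phases are offset by
`peak_phase − 0.25` (default +0.25); shift values are unaffected.
Linearization regresses the nodes inside the conventional circadian-time
windows — CT 6–22 h for D, CT 18–34 h for L, centered on the phases used
during diurnal entrainment — and extends the line periodically with a
single one-cycle offset jump at a breakpoint placed diametrically opposite
the window midpoint (overridable; the placement is otherwise a judgment
call).  Note that a one-cycle jump is invisible modulo 1, so the
linearized and purely linear maps generate identical wrapped dynamics;
the breakpoint matters only for the shape of the stored function.

Uncertainty propagates by non-parametric bootstrap at two levels: slope
bootstrap (resampling in-window nodes, 500 draws per function) and
master-dataset bootstrap (resampling whole trajectories with replacement
from the pooled step + control set, default 1000 resamples, each refitting
shared periods and phases end to end).  Resamples lacking a control in
either condition or with fewer than three distinct step phases per
direction are redrawn and counted.

## Linear theory

With linear L and D the dawn-to-dawn composition is affine with contraction
c = (1−l)(1−d); stability requires |c| < 1 (l = d = 0 is marginal and
reported as such).  The closed-form fixed point is screened against one
iteration of the actual wrapped map to select the winding integer; if the
entrained phase would sit across a breakpoint, no fixed point is claimed.
Differentiating the entrained post-dawn phase with respect to day length
and converting to peak time gives

    m = 1 − [1 − (1−l)·ρ]/(d + l − l·d),  ρ = ω_D/ω_L,

equal to (1−l)(ρ−1+d)/(d+l−ld) and to d(1−l)/(d+l−ld) at ρ = 1.  The
equal-frequency special case was re-derived here from the fixed point
because the general printed form available to us was typographically
garbled; the derivation is validated two independent ways in the tests
(numerical dt_pk/dτ of the closed-form fixed point over 100 random
parameter draws, and regression on map-simulated peak times, both to
1e−5–1e−6), and its plug-in value at (0.34, 0.38, 0.93) is 0.346.

The β-model (Δt_pk = θ̂_t/(ω_L β₂) + δ(1+β₁/β₂) + C₁;
t_pk = τ(1−β₁−β₂) + Tβ₁ + C₂) is kept as a distinct parameterization; the
library asserts no conversion between (l, d) and (β₁, β₂).  The test suite
does use the correspondence β₂ = 1/(d+l−ld), β₁ = −(1−l)ρ/(d+l−ld) —
derived independently from the step-decomposition of a dark pulse — as an
oracle connecting the simulated PRC slope to the closed form.

The global fit minimizes χ² = Σ((y−ŷ)/σ)² over six parameters (β₁, β₂ and
four intercepts: PRC left/right of a configurable breakpoint, wedge,
entrainment).  For fixed (β₁, β₂) the intercepts are weighted means of the
residuals, so they are profiled out and the optimization is 2-D
least-squares from a seeded multi-start; 95% CIs come from the curvature
(J'J)⁻¹ at the optimum.  Reduced χ² uses N−6 degrees of freedom.
Rank-deficient designs (e.g. seasonal data at a single day length) are
detected by SVD of J'J and rejected with the unconstrained parameter named.

## Geometry

The geometric model fixes the day orbit as the unit circle at the origin
and the night orbit (radius R, center (0, X) — the +y axis choice is
observationally irrelevant by rotational symmetry, which is asserted by a
rotation test).  In the instantaneous limit, transitions are radial jumps
to the nearest point of the target orbit; the jump is undefined exactly at
the target center, and trajectories that hit it are treated as failed
entrainment.  Entrainment over 30 cycles is judged on dawn phases (cycle
29 vs 30 and two initial phases π/4, 5π/4, tolerance π/180 rad), and the
phase-vs-day-length relation is called linear when the mean absolute fit
error is below 10% of the phase spread.

Relaxed variants integrate the radial attraction explicitly:
ṙ = −a(r − R_orb) toward circles (half-time ln 2/a), a signed-distance
attraction plus the ellipse-tracking term toward ellipses, and angular
velocity θ̇ = ω(1 + (ε/ω) sin ωt) for speed modulation (modulation clock
restarting at each dawn by default, absolute-time option available).  The
printed form of the ellipse radial law we worked from has the tracking term
with a sign under which an oscillator starting on the ellipse would leave
it; the implementation uses ṙ = −a·d_signed + ṙ_ellipse, verified by the
on-orbit invariance test.  Circular variants propagate segments in closed
form (exact); the generic path is fixed-step RK4 (dt = 0.01 h default,
convergence under refinement tested), with the ellipse nearest point found
by bounded minimization over the parameter angle within ±π/2 of the polar
angle.  Cycle counts per variant: 30 (instant), 10 (attraction, velocity),
4 (ellipse).  Dynamical variants score entrainment on peak times — the
first crossing of θ = π/2 after the radius has relaxed to within 1% of the
orbit following the final dawn — and additionally require the linear-fit
error to exceed 0.5 h as well as 10% of the spread before a cell is called
non-linear.

## Synthetic data

The generators emulate the study designs: 30-min reporter sampling with
4–8 technical replicates and additive Gaussian noise on the normalized
scale (default σ = 0.1, a typical replicate scatter for plate-reader
bioluminescence), dark samples emitted but flagged, and a decaying
exponential masking transient (amplitude 3, time constant 1 h) in the
first 2.5 h after lights-on to exercise the exclusion logic; 15-min
in-vitro-style sampling for step experiments, with the stepped reaction
switching period and applying the truth's shift at the step; and
PRC/wedge/seasonal designs on the grids of the driven experiments (12 h
pulses across the cycle, δ = 8–16 h near subjective dusk, T = 22–26 h with
τ = 8–14 h).  Responses come from the closed-form β-model or from full
phase-oscillator simulation of an L/D truth.  The default reporter waveform
is sinusoidal in phase; real reporter waveforms are asymmetric and
multi-peaked, so passing recovery tests here demonstrates correctness of
the estimation machinery, not robustness to real waveform shape — the
skewed-sine option (off by default) probes the leading asymmetry effect,
which is the divergence between parabolic and sinusoidal peak estimates.

## Problem sizes and defaults

Simulation sizes used by the tests and the acceptance script: 10 driving
cycles for seasonal entrainment (1000 for driving-period scans, with the
last 950 recorded), a day-length grid of 4–18 h in 0.1 h steps for the
entrainment census, 1000 draws for slope-uncertainty propagation, 20 seeded
datasets for recovery checks, and a 12×12 log-spaced (R, X) grid for the
geometry sweep.  Entrainment is declared when the wrap-aware sample SD of
the last five dawn phases is below 0.01 cycles; the speed of entrainment is
the first sliding 3-cycle window whose wrapped sample variance drops below
0.01 cycles² (the wrap-aware variance equals the plain variance away from
the 0/1 boundary and fixes the artifact on it).

## Known limitations

Amplitude dynamics, stochastic phase diffusion, and multi-oscillator
coupling are out of scope (the geometry module covers amplitude only
through the planar relaxation variants).  Counts-level (shot) noise is not
modeled; noise is Gaussian on the normalized scale.  The breakpoint of a
linearized step function and of the PRC is a configurable input, not an
estimated parameter (an optional χ² scan over candidate breakpoints exists
in the global fit driver but is an extension).  The (l,d) ↔ (β₁,β₂)
correspondence is used only as a test oracle, not exposed as API.  The
entrained fixed point is only claimed on the principal branch; entrained
states that straddle a breakpoint must be obtained by iterating the map.
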