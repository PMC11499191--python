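# Methods

## Model

Gait adaptation and de-adaptation are modeled at the stride level. Each
stride contributes one symmetry-index value per gait parameter,
`SI = (L − R)/mean(L, R) × 100` (%), negative when the right-side value is
larger; the index is antisymmetric under side exchange, scale-invariant,
and bounded in (−200, 200) for positive inputs. Within an experimental
stage the expected SI trajectory is a sum of one or two exponentials of
elapsed time plus an offset,

    SI(t) = a·e^(−bt) + d·e^(−ft) + c,

with time measured in **seconds since the fitted window's onset** at the
actual (non-uniform) stride timestamps. The decay constants `b`, `f`
(1/s) are the quantities of scientific interest: in the two-component
model the larger constant is labeled the *explicit* (fast) adaptation
process and the smaller the *implicit* (slow) one, with amplitudes
re-associated accordingly; an exact tie is reported as degenerate rather
than broken arbitrarily.

Assumptions: additive, independent, homoscedastic Gaussian stride noise
(this is what least-squares fitting and the Shapiro–Wilk residual check
presume); stage-wise stationarity of the underlying curve; instantaneous
belt-speed and cue transitions at stage boundaries.

## Trial protocols

All six trials run 1380 s: baseline [0, 180), adaptation halves
[180, 630) and [630, 1080), post-adaptation [1080, 1380), with half-open
windows so boundary strides belong to exactly one stage. Split-belt
stages set left/right belts to 4/3 and 2/3 of comfortable speed;
asymmetric cueing splits the comfortable stride time 2:1 (or mirrored
1:2) between left and right cues; symmetric cues during split-belt stages
keep the auditory load comparable. Control trials (`TS`, `TC`) carry the
same intervention in both adaptation halves so downstream truncation is
uniform: their adaptation fit uses only the first 7.5 min (comparable
steady state with sequential trials), whereas sequential trials fit the
second half, where re-adaptation unfolds. Post-adaptation fits always use
[1080, 1380). Trial-order randomization uses a cyclic Latin square seeded
by the input order; any permutation of the six codes yields a valid
square.

The step-time asymmetry imposed by a cueing stage follows in closed form
from the cue durations (±66.67% at 2:1). Split-belt stages and step
length under cueing have no closed-form target; the corresponding
steady-state asymmetries are free ground-truth parameters of the
generator, and `imposed_asymmetry` returns an explicit "undefined"
(`None`) rather than a guess.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not gait biomechanics:

- **Stride timing** — durations are the comfortable stride time with 2%
  Gaussian jitter; timestamps are their cumulative sums, so series are
  non-uniformly sampled and fitting must not assume uniform spacing.
- **Mean trajectory** — per curve segment a double exponential with time
  re-zeroed at segment onset. Consecutive stages holding equal curves
  (control-trial adaptation halves) form one uninterrupted 900 s segment.
  Defaults: fast decay 0.05 1/s (τ = 20 s), slow decay 0.005 1/s
  (τ = 200 s), 60% of the approach carried by the fast component.
- **Targets** — split-belt steady states default to 15% (step length) and
  10% (step time), typical healthy-adult magnitudes on 2:1 belts; cueing
  attains 30% of its prescribed ±66.67% step-time asymmetry by default
  (cue-following is imperfect), scaled further by a compliance factor in
  [0, 1]; the spatial response to cueing defaults to ±5%.
- **Aftereffect** — post-adaptation starts at −0.6 × the late-adaptation
  value (opposite sign) and decays to zero. The magnitude is a stand-in:
  the source literature reports the phenomenon qualitatively.
- **Savings / interference** — positive multipliers on the fast decay
  constant of the second adaptation half of congruent / incongruent
  sequential trials (defaults 1.0 = no effect).
- **Noise** — i.i.d. Gaussian per stride, default sd 1%; the simplest
  structure consistent with residual-normality checking. No
  autocorrelation, drift, missing strides, or compliance dynamics.
- **Recordings** — stride series can be rendered as 100 Hz heel-position
  and vertical-force channels: piecewise-linear heel trajectories (land
  one step length anterior to the stance foot, translate backward with
  the belt, linear swing), trapezoidal body-weight force pulses whose
  ramps span several samples, and stance ending 0.11 s after the
  contralateral heel strike so double support survives asymmetric
  timing. Ground-truth events are returned alongside for closure tests.
- **Cohort-level decay tables** — for exercising the statistics battery
  in isolation, decay constants are drawn log-normally around the
  component base rates: a between-subject multiplier (σ = 0.3, shared
  within subject, cancels in within-block ranking) times an independent
  within-subject multiplier (σ = 0.4) times any condition effect. These
  spreads reproduce the order-of-magnitude heterogeneity of
  healthy-cohort adaptation rates while keeping a doubled rate detectable
  at n = 10.

Passing tests on this generator demonstrate pipeline correctness and
statistical calibration under the stated noise model; they do not
establish robustness to autocorrelated noise, non-compliance episodes, or
marker artifacts present in real recordings.

## Event detection

Heel strikes are upward crossings of each vertical force channel through
0.05 × body weight, linearly interpolated between samples, with a
refractory window of a quarter stride time; non-alternating contacts are
dropped with a warning. Step length is the heel-to-heel anterior-
posterior distance at the leading foot's contact; because both heels
translate with the belts during stance, the separation is read by linear
extrapolation from the two samples after the event back to the event
time, cancelling belt-induced drift (without this, split-belt step
lengths carry an O(1.5%) bias at 100 Hz). Step time is the interval from
the contralateral to the ipsilateral contact. On simulated recordings
detection recovers event times within 2 ms and step lengths within 0.3%.

The stride-level Butterworth filter takes a normalized cutoff as a
fraction of the stride-sequence Nyquist frequency, defaulting to 1.0 — a
mathematical pass-through, since a cutoff at Nyquist has unit gain (a
50 Hz cutoff on a 100 Hz recording is likewise a no-op). 0.1 is a
recommended value when visible smoothing is wanted. The filter is a
forward single pass initialized at the first sample's steady state, so a
constant series is exactly preserved.

## Curve fitting

`pso_fit` minimizes the residual sum of squares with a global-best
particle swarm: velocity update `v ← wv + c₁r₁(pbest−x) + c₂r₂(gbest−x)`,
positions clamped to the bounds, velocities clamped to 20% of each bound
span. Defaults: swarm 50, w = 0.729, c₁ = c₂ = 1.494, ≤ 500 iterations,
convergence declared when the global best improves by < 1e−10 over 25
consecutive iterations (an unconverged best run is returned flagged,
never silently).

Double-exponential least squares has a well-known spurious basin in which
both decay constants merge into one intermediate timescale. Three
measures make the global optimum reliably reachable:

- **Data-scaled bounds** — decay constants span [1e−4, 1] 1/s (the band
  identifiable from 450–900 s windows); amplitude bounds default to
  ±4 × the observed data range (zero-centered) and the offset to the data
  midrange ± 4 ranges, clipped to the ±200% symmetry-index envelope.
  A swarm spread over a fixed ±200% box wastes nearly all of its density
  when real amplitudes are ~10%.
- **Scale-aware initialization** — decay dimensions are seeded half
  log-uniformly (scale parameters), half uniformly.
- **Stratified restarts** — four independent swarms by default, cycling
  initialization strata; two of them seed the decay pair in separated
  log-decades (fast high, slow low, and mirrored). The lowest-cost run
  wins.

With these defaults the fitted optimum matches a truth-initialized
`scipy.optimize.curve_fit` solution exactly (identical error medians and
maxima over seeded benchmarks), i.e. remaining estimation error is
statistical, not optimizer-induced. At the reference condition (900 s
window, amplitudes 10%/5%, decays 0.05/0.005 1/s, 1% noise) the median
relative error of the decay constants is ~11% (fast) and ~4% (slow). The
optimizer is deterministic given its seed; restarts draw from spawned
seed sequences.

## Model selection

Least-squares AIC with the error variance counted as a parameter:
`AIC = n·ln(RSS/n) + 2(p+1)`, p = 3 (single) or 5 (double); only
differences are meaningful, the lower value wins, and an exact tie goes
to the single model by parsimony. AICc is available but off by default —
per-stage stride counts are in the hundreds, making the correction
negligible. A perfect fit (RSS = 0) leaves the criterion undefined and
raises. Residuals of both models are checked with Shapiro–Wilk and
exportable as QQ point sets (Blom plotting positions).

One calibration fact worth knowing: when the data truly come from a
single exponential, the double model overfits by roughly a χ²(2) improvement
and AIC's penalty difference of 4 accepts that overfit with probability
≈ e^(−2) ≈ 13.5%. Single-model data are therefore correctly classified in
only ~86% of replicates — a property of AIC itself, not of the optimizer
(a sharper optimizer can only lower the double model's RSS further).
Double-model data at the reference condition are classified correctly
essentially always.

## Statistics battery

The normality gate runs Shapiro–Wilk per condition; any p < 0.05 (or a
degenerate constant condition) routes to the nonparametric branch, which
is the branch implemented. Friedman's test is computed from within-block
average ranks with the standard tie correction and a χ²(k−1) reference;
it is validated against `scipy.stats.friedmanchisquare` at k ≥ 3 and
supports k = 2, where its decision coincides with the exact sign test at
α = 0.05 for n = 10 continuous data. Post-hoc Wilcoxon signed-rank tests
drop zero differences and report a **signed** Z from the positive-rank
sum with average-rank tie handling and tie-corrected variance, by default
without continuity correction — the convention under which ten uniformly
signed distinct differences give Z = −2.803 — with continuity and exact
modes available; the battery falls back to the exact null automatically
when fewer than five nonzero differences remain. Pairwise p-values are
uncorrected by default (a Holm option exists). Families compared: (TS,
TCS, TcS), (TC, TSC, TSc), and (TS, TC), per parameter × component ×
stage, with pairwise tests only after a Friedman rejection at α = 0.05,
and listwise exclusion of subjects with any missing cell in a family.

Calibration on cohort-level simulated decay tables (n = 10): pooled
Friedman type-I error ≈ 4% at the nominal 5%, and ≥ 85% detection of a
×2 facilitation of the explicit constant in the affected family cell.

## Problem sizes in the test suite

Unit tests run single trials (≈ 1250 strides) and reduced-budget swarm
configurations where only bookkeeping is under test. The end-to-end
checks use 20 seeds for parameter recovery, 50 seeds per direction for
model discrimination, 200 seeds for statistics calibration and power, a
201³-point grid for the optimizer-oracle comparison, and a two-subject
six-trial cohort for the pipeline structure test — sizes at which the
Monte-Carlo bands quoted above are comfortably resolved.

## Known limitations

- The generator's aftereffect magnitude, cueing attainment, split-belt
  steady states and decay-rate spreads are plausible defaults, not
  empirical estimates; all are exposed in configuration.
- Only the nonparametric statistical branch is implemented; the gate
  reports when a parametric analysis would have been admissible.
- Step length is computed in the laboratory frame at heel strike; no
  belt-frame correction or marker gap handling.
- At most two exponential components; no power-law alternative.
- The compliance scalar is static — real cue-following waxes and wanes,
  which the fitting stage would see as structured residuals.
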