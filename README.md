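# gaitadapt

Analysis pipeline for locomotor adaptation experiments that combine
**split-belt treadmill (SBT)** walking and **asymmetric rhythmic auditory
cueing (ARAC)** — for motor-control and gait-rehabilitation researchers who
want to quantify how fast people acquire, and lose, an imposed gait
asymmetry, and whether one intervention's working motor memory facilitates
(or interferes with) adaptation to the next.

## What it computes

Every stride yields a symmetry index for a spatiotemporal gait parameter
(step length or step time):

    SI = (L − R) / mean(L, R) × 100   [%]

negative when the right side dominates. During an adaptation or
post-adaptation stage, the per-stride SI series is fitted with single- and
double-component exponentials of elapsed time *t*:

    SI_single(t) = a·e^(−bt) + c
    SI_double(t) = a·e^(−bt) + d·e^(−ft) + c

by a bounded global-best **particle swarm optimizer** minimizing the
residual sum of squares. The two models are compared with the
least-squares **AIC** (`n·ln(RSS/n) + 2(p+1)`; lower wins). In the double
model the larger decay constant is the **explicit** (fast, cognitively
driven) adaptation process, the smaller the **implicit** (slow,
use-dependent) one. Decay constants assembled per subject × trial × stage
× parameter × component are compared across condition families with a
Shapiro–Wilk normality gate, **Friedman tests** and post-hoc **Wilcoxon
signed-rank** tests.

Six trial protocols are supported — SBT alone (`TS`), ARAC alone (`TC`),
and the four sequential combinations (`TSC`, `TCS` congruent; `TSc`, `TcS`
incongruent) — each 23 min: 3 min baseline, 15 min adaptation (split into
two 7.5 min halves for sequential trials), 5 min post-adaptation. During
SBT the left belt runs at 4/3 and the right at 2/3 of the comfortable
speed (ratio 2, mean preserved); during ARAC the left/right cue durations
are 2/3 and 1/3 of the comfortable stride time.

A first-class synthetic-data module generates stride tables and full
100 Hz marker/force recordings with known ground truth (two-timescale
approach to the imposed asymmetry, opposite-sign aftereffects, per-stride
Gaussian noise, savings/interference modifiers), so every stage of the
pipeline is verifiable by parameter recovery.

## Worked example

Simulate a ten-subject cohort in which the congruent second adaptation
half benefits from a ×2 savings effect on the fast decay constant, then
run the full pipeline:

```bash
cat > cohort.yaml <<EOF
subjects: 10
seed: 11
noise_sd: 1.0
comfortable_speed_mps: 1.1
comfortable_stride_time_s: 1.1
truth:
  savings_multiplier: 2.0
EOF
gaitadapt simulate --config cohort.yaml --out demo
gaitadapt analyze --manifest demo/manifest.yaml
gaitadapt report --results demo/results
```

which prints:

```
wrote 60 trials and manifest.yaml to demo
fits: 480 rows; decay table: 480 rows; battery: 36 tests; failures: 0
36 tests; 4 significant Friedman comparisons at alpha=0.05:
  TS|TCS|TcS | step_length explicit adaptation: chi2=15.20 p=0.0005
  TS|TCS|TcS | step_time explicit adaptation: chi2=12.60 p=0.0018
  TC|TSC|TSc | step_length explicit adaptation: chi2=7.54 p=0.0231
  TC|TSC|TSc | step_time explicit adaptation: chi2=15.20 p=0.0005
```

Reading the output: 480 fit rows are 10 subjects × 6 trials × 2 stages
(adaptation, post) × 2 parameters × 2 model kinds; the decay table holds
the explicit/implicit constants of every double fit. The battery's 24
Friedman tests plus follow-up Wilcoxon pairs flag exactly the cells where
the simulated savings effect lives — the explicit adaptation rate in both
intervention families — and nothing else: de-adaptation rates and implicit
components stay null, as generated.

The library surface mirrors the CLI: `build_protocol`,
`simulate_asymmetry_series` / `simulate_recording`, `detect_steps`,
`symmetry_index`, `pso_fit`, `compare_models`, `run_battery`, and
`run_pipeline` are all importable from `gaitadapt`.

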