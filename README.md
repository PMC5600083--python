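# volbandit

Analysis toolkit for a two-armed probabilistic reward-learning task with
stable and volatile phases. The package simulates the task's reward
schedules, models choices with a grid-based Bayesian volatility observer and
competing strategy regressors, estimates per-subject delta-rule learning
rates in stable vs volatile windows, and runs the associated reversal-slope
and group-level analyses — all exercisable end-to-end on synthetic cohorts.

## The task

Two options (`A`/`B`) are presented on every trial with displayed reward
magnitudes that always sum to 100 points; exactly one option is rewarded.
Variants:

* **short** — 80 stable trials (75:25 in favour of `A`), then 80 volatile
  trials whose majority option flips every 20 trials (80:20 / 20:80);
* **long** — 120 stable trials and 170 volatile trials with a
  30-40-30-40-30 switch structure (phase order configurable);
* **familiarization** — one 20-trial block at 80:20.

## Modules

| module | role |
| --- | --- |
| `volbandit.schedule` | schedule generation with exact per-block reward ratios, CSV trial-log I/O |
| `volbandit.ideal_observer` | joint grid filter over reward probability, log-volatility and its drift; exports trial-wise E[r], E[v] |
| `volbandit.agents` | synthetic subjects: delta-rule learner (condition-dependent learning rate), ideal-observer agent, win-stay-lose-shift, alternator, value-follower, random; cohort simulation with ground-truth logging |
| `volbandit.glm_compare` | per-subject logistic GLM with constant + four strategy regressors (ML with a Firth fallback under separation), group summaries and chi-squared proportion tests |
| `volbandit.learning_rate` | windowed maximum-likelihood (alpha, beta) fits of the delta-rule + logistic-selector model; condition contrasts with CIs |
| `volbandit.reversal` | trailing 4-trial running averages, post-switch regression slopes, interval mixed ANOVA with repeated contrasts |
| `volbandit.group_stats` | mixed/repeated ANOVA, paired & Welch t-tests, CIs, correlations (thin pingouin/scipy wrappers pinned by fixture tests) |

## Command-line pipeline

```bash
simulate-schedule --variant short --seed 7 --out trials.csv
ideal-observer    --trials trials.csv --out traj.csv

simulate-cohort   --config cohort.yaml --out-dir cohort/
compare-models    --cohort-dir cohort/ --out fits.csv --summary-out summary.csv
fit-learning-rates --cohort-dir cohort/ --variant short --out rates.csv
reversal-slopes   --cohort-dir cohort/ --out slopes.csv
report            --rates rates.csv --slopes slopes.csv --out report.json
```

A cohort config is YAML:

```yaml
seed: 3
schedule: {variant: short, seed: 0}
groups:
  - label: children
    n_subjects: 30
    kind: delta_rule
    alpha_stable: {loguniform: [0.08, 0.3]}
    alpha_volatile: {loguniform: [0.2, 0.6]}
    beta: {fixed: 5.0}
```

## Conventions

* Option `A` is the option most often rewarded in the initial stable phase;
  choice indicators are 1 = chose `A`. Blue/green labelling is presentation
  only and handled at I/O time.
* Trial indices are 1-based and windows are inclusive (`stable` short window
  = trials 20-80).
* The logistic selector operates on expected values computed with
  magnitudes rescaled to [0, 1], so inverse temperatures have a
  conventional softmax scale.
* Learning rates are natural-log transformed for group statistics.
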