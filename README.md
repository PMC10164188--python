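# phasefit

Two-phase piecewise-linear learning-curve modelling for daily
cognitive-training data.

When children train working memory daily for weeks on an adaptive task,
their performance improves through two superimposed processes: a fast
**task-specific** gain (strategy, interface, task familiarity) that
saturates within the first days, and a slow **capacity** gain that keeps
growing throughout.  `phasefit` separates the two per subject by modelling
the daily score `y_t` as a piecewise-linear curve with a hidden switch,

```
phase 1:  y_t = (beta_cap + beta_ts) · t + alpha + w_t
phase 2:  y_t =  beta_cap · t + Delta_TS + alpha + w_t ,   Delta_TS = beta_ts / tau
```

where the hidden phase follows a two-state left-to-right Markov chain
(start in phase 1, switch with per-day probability `tau`, never return)
and `w_t ~ N(0, sigma²)`.  Each subject's five parameters
`(beta_cap, beta_ts, alpha, tau, sigma)` are estimated by
expectation–maximization; the E-step yields a posterior over the
**transition day** (the last day of the fast phase, constrained to the
first 10 days), whose posterior mean is the reported estimate.

The package contains four building blocks, usable independently:

- `phasefit.data` — long-format training CSVs, transfer-test panels
  (4 tasks × 5 sessions), and the cohort preprocessing pipeline:
  exclusion of subjects missing ≥ 6 transfer tests, 35-nearest-neighbour
  imputation, standardization to first-session mean/sd.
- `phasefit.model` — the HMM: emissions, transition-day posterior, EM
  fitting (`fit_em`), derived quantities (`delta_ts`,
  `estimate_transition_day`, `flag_outliers`).
- `phasefit.simulate` — synthetic cohorts with known ground truth:
  piecewise-linear trajectories (`alpha ~ U(2,4)`, `beta_ts ~ U(0.8,1.6)`,
  `beta_cap ~ U(0.01,0.1)`, integer switch day 1–10, 22 daily
  observations, Gaussian noise) and dual-process transfer panels.
- `phasefit.recovery` — the parameter-recovery study: fit a simulated
  cohort and report bias, RMSE and within-k-day transition accuracy.

See `docs/methods.md` for the model, estimation details and known
identifiability limits, and `examples/` for narrative scripts.

## Worked example

Fitting one simulated subject (`python examples/fit_one_subject.py`):

```
true:   alpha=3.250  beta_ts=1.518  beta_cap=0.0798  transition day=9
fitted: alpha=3.059  beta_ts=1.550  beta_cap=0.0846  tau=0.115  sigma=0.297
transition day: posterior mean 8.60, MAP 9 (loglik -6.96, 23 EM iterations)
posterior over the transition day: [0.    0.    0.    0.    0.    0.    0.001 0.399 0.601 0.   ]
accumulated task-specific gain delta_ts = 13.53 levels
```

The posterior concentrates on days 8–9 around the true switch after day 9
(the switch-day observation is consistent with both phases, so its mass is
always shared with the preceding day).  `delta_ts = beta_ts / tau ≈ 13.5`
levels is the total fast-phase gain — here the subject improved ~13.5
levels through the task-specific process before it saturated, on top of the
slow capacity drift of `beta_cap ≈ 0.08` levels/day.

Scoring a 100-subject recovery study (`python examples/recovery_study.py`):

```
n = 100 subjects (0 non-converged)
          beta_cap: bias +0.0045   rmse 0.0235
           beta_ts: bias -0.1194   rmse 0.3770
             alpha: bias +0.1937   rmse 0.5866
    transition_day: bias -0.3522   rmse 0.7154
  within 1 day(s): 92.0%
  within 2 day(s): 99.0%
```

so at the reference noise level the switch is located within one day for
~9 of 10 subjects, and the slow capacity slope is recovered essentially
without bias.

## Command line

A thin CLI chains the stages:

```sh
phasefit simulate --n 1000 --seed 1 --out sim/ --mkdir
phasefit fit      --input sim/training.csv --out fits.csv
phasefit recover  --fits fits.csv --truth sim/truth.csv --out report.json
phasefit study    --n 1000 --seed 1 --out study/ --mkdir   # all of the above
```

Every artifact embeds the package version, seed and resolved
configuration; per-subject failures are flagged rows, never aborts.

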