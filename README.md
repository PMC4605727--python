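# doserisk

Excess-odds-ratio dose-response modelling for screening cohorts with
uncertain dosimetry.

Radiation-epidemiology screening studies — the canonical case being thyroid
cancer prevalence among people exposed to ¹³¹I as children — estimate the
dose-response from reconstructed organ doses that carry substantial
measurement error. Modern dosimetry systems express that uncertainty as a
set of *stochastic dose realizations*: hundreds of alternative cohort dose
vectors, correlated between subjects through shared (cohort- or group-wide)
error components and scattered per subject through unshared ones. Classical
(unshared) error biases a naive dose-response slope toward the null; shared
error leaves the point estimate roughly alone but should widen its
uncertainty interval.

`doserisk` implements the full analysis chain for this setting, for
biostatisticians and radiation epidemiologists working in Python:

- **Risk model** (`doserisk.risk`) — a logistic model for prevalent disease
  whose odds ratio at dose *D* (Gy) is `1 + EOR(D)` with

  `EOR(D) = α·D·exp(γ·D + κ(e−8) + τ(a−22) + η·1[male])`

  on top of a baseline adjusted for gender, region (oblast) and categorical
  screening age; `α` is the excess odds ratio per Gy, `γ` allows curvature,
  and `κ, τ, η` modify the dose effect by age at exposure *e*, age at
  screening *a*, and sex.
- **Dosimetry simulation** (`doserisk.dosimetry`) — ecological/instrumental
  dose equations on tabulated thyroid-activity profiles, and a
  two-dimensional Monte Carlo generator of correlated dose-realization
  matrices from declarative shared/unshared error specifications.
- **Cohort simulation** (`doserisk.cohort`) — synthetic screening cohorts
  with configurable covariate marginals, lognormal true doses, outcomes
  drawn from the risk model, and an exclusion-flag stage.
- **Inference** — maximum likelihood with profile-likelihood CIs and
  likelihood-ratio tests (`doserisk.ml`), on deterministic doses
  ("unadjusted") or per-subject realization means (**regression
  calibration**); **Monte Carlo maximum likelihood** (`doserisk.mcml`),
  which maximizes the likelihood averaged over whole-cohort dose
  realizations; and **Bayesian MCMC model averaging** (`doserisk.bayes`)
  over the realization index with a collapsed Dirichlet(1) prior, reporting
  maximum-posterior estimates, 95% credible intervals, DIC and Gelman–Rubin
  PSRF.
- **Pipeline** (`doserisk.pipeline`) — one configuration object, all four
  routes, a comparative report table.

## Worked example

`examples/full_comparison.py` simulates one cohort (3,000 subjects, ~150
prevalent cases, true α = 1.5/Gy, 25 correlated dose realizations per
subject), applies the exclusion stage, and fits the dose-free and linear
models by all four routes:

```
| method | model | fit stat | df | p | alpha (95% CI) | ... | % change alpha |
|---|---|---|---|---|---|---|---|
| unadjusted             | null | 1280.797 | 2993 | -     | -                 | - |
| unadjusted             | aD   | 1220.816 | 2992 | 0.000 | 1.03 (0.57, 1.77) | 0.0 |
| regression_calibration | null | 1280.797 | 2993 | -     | -                 | - |
| regression_calibration | aD   | 1222.529 | 2992 | 0.000 | 0.82 (0.46, 1.41) | -20.2 |
| mcml                   | null | 1280.797 | 2993 | -     | -                 | - |
| mcml                   | aD   | 1221.072 | 2992 | 0.000 | 0.89 (0.48, 1.56) | -13.9 |
| mcmc                   | null | 1294.760 | 2993 | -     | -                 | - |
| mcmc                   | aD   | 1232.969 | 2992 | -     | 0.95 (0.53, 1.70) | -8.3 |
```

Reading the linear (`aD`) rows: the dose trend is highly significant
(likelihood-ratio p < 0.001 against the dose-free model); the unadjusted
fit estimates an excess odds ratio of 1.03 per Gy (the odds of prevalent
disease at 1 Gy are about twice the zero-dose odds); the three
error-correction routes move the estimate by −20% to −8% on this data set
and carry the dosimetric uncertainty into their intervals. The `mcmc` rows
report DIC instead of deviance and the marginal maximum-posterior estimate
with a 95% credible interval.

The other examples each exercise one capability and print what the numbers
mean: `dose_equations.py` (ecological vs instrumental dose),
`dose_realizations.py` (shared/unshared realization structure and
per-subject dose GSDs), `fit_dose_response.py` (profile CIs and LRTs),
`mcml_fit.py` (likelihood averaging and interval widening),
`bayesian_fit.py` (posterior summaries and convergence diagnostics).

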