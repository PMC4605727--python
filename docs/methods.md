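# Methods

## The risk model

For subject *i* with age at screening *a* (years), age at exposure *e*
(years), sex *s* and true thyroid dose *D* (Gy), the probability of being a
prevalent case is

    p_i = x_i / (1 + x_i),
    x_i = exp[ β₀ + β_s·1(male) + Σ_m β^o_m·1(oblast m) + Σ_k β^a_k·1(a ∈ A_k) ]
          · ( 1 + α·D·e^{γD + κ(e−8) + τ(a−22) + η·1(male)} )

so `1 + EOR(D)` multiplies the baseline odds. The ages are centred at 8
(exposure) and 22 (screening) years — near the cohort means under the
default simulation design — which decorrelates the modifier terms from the
main slope and stabilizes optimization. The model is defined only where
`1 + EOR > 0` for every subject in the data; the fitted α therefore has an
implicit lower bound near `−1/max(D)`.

Model ladders are expressed as `ModelSpec` objects or compact labels
(`"null"`, `"aD"`, `"aD*exp(gD)"`, `"aD*exp(gD+k(e-8))"`, `"aD*exp(gD+t(a-22))"`,
`"aD*exp(gD+s)"`). Baseline screening-age categories default to cohort
quartiles (the adjustment structure matters more than the exact bins, which
are a free design choice); reference categories are female, the
lexicographically first oblast, and the lowest age category.

## Dosimetry

`ecological_dose` integrates a tabulated ¹³¹I thyroid-activity time course
over the exposure window `[0, T]` (default T = 66 days) by the trapezoid
rule on the supplied grid and converts to absorbed dose with
`U_c·E_th/m_k`, where `U_c = 13.82` is the composite unit-conversion
factor, `E_th` the mean energy absorbed in the thyroid per decay (default
0.19 MeV, configurable — the appropriate value depends on thyroid mass and
geometry), and `m_k` the thyroid mass in grams. `instrumental_dose`
rescales it by the measured/modelled activity ratio at the measurement
time, assuming the modelled time course has the correct shape.

Stochastic dose sets come from a two-dimensional Monte Carlo: each
realization column draws every *shared* parameter once per sharing group
and every *unshared* parameter once per subject, and multiplies the factors
onto the true dose. Columns are the correlation unit; subjects sharing a
group move together within a column. Multiplicative factors reproduce the
lognormal-like per-subject dose spreads such systems report without
re-running a transport model; they are a structural stand-in, not a
dosimetry reconstruction. All randomness flows from one master seed
expanded into recorded per-column seeds.

Two centering conventions are supported for lognormal factors: unit median
(the default; per-subject median realized dose converges to the true dose)
and unit mean (`center="mean"`; the per-subject realization average is
unbiased for the true dose — the right convention when realizations stand
for posterior dose draws, as in the error-correction experiments).
`posterior_dose_realizations` additionally emulates a two-stage system
that first observes a classically mismeasured central estimate and then
draws from the posterior of the true dose under the cohort lognormal dose
prior.

### Default error budget

Five factors: two shared lognormal transport terms (GSD 1.10 each) and
three unshared terms — thyroid mass (GSD 1.25), biokinetics (GSD 1.15) and
a dominant activity-measurement term whose log-sd varies by subject,
drawn once per cohort from Lognormal(ln 0.375, 0.55) truncated at 1.62.
This yields per-subject total dose GSDs spanning ≈1.35–5.2 with arithmetic
mean ≈1.76 and geometric mean ≈1.72, with most of the uncertainty unshared
— the structure reported for stochastic ¹³¹I thyroid dosimetry in the
Belarus screening cohort. The real system's 59 parameter distributions are
not public; only this structure is emulated.

## Synthetic cohorts

Defaults emulate the Belarus screening study's shape: N = 11,611 analysed
subjects; age at exposure uniform on [0, 18) years; screening delay uniform
on [10, 18] years (screening age centred near 22); gender 1:1; three
equiprobable oblasts; true doses lognormal with arithmetic mean 0.68 Gy and
log-sd 1.6 (spanning roughly half a mGy to tens of Gy at cohort scale);
case indicators Bernoulli from the risk model at the *true* dose, with the
intercept calibrated by root finding so the expected case count matches a
target (default 87). Exclusion flags (bad ID, ineligible age, poor
measurement, not interviewed, prior disease) are simulated attributes with
rates matching the study's published tallies; `apply_exclusions` applies
them in order, counting each subject under its first matching rule.

What the generator does *not* emulate: dose–covariate dependence (a hook is
provided but defaults to independence), screening attendance and diagnostic
sensitivity, latency, and any spatial structure below the oblast label.
Passing tests therefore demonstrate the estimators' behaviour under the
assumed error mechanisms, not the clinical realism of the cohort.

## Estimation routes

**Unadjusted / regression calibration.** Maximum likelihood on a single
dose vector — the matrix's deterministic (central) doses, or the
per-subject arithmetic mean of realizations, which approximates the
expected true dose given all dosimetry information. Optimization is
L-BFGS-B on the unconstrained parameters with analytic gradients; points
violating `1 + EOR > 0` return a continuous soft-clipped penalty (the
likelihood with `1 + EOR` floored at 1e−6 inside the log, minus a linear
restoring term of slope 1e4, bounded below by −1e8). A hard penalty cliff
was tried first and abandoned: it broke quasi-Newton line searches whenever
the MLE sat near the boundary `−1/max(D)`. On failure the fitter retries
with jittered starts and a Nelder–Mead polish (up to 5 restarts);
convergence is declared at gradient ∞-norm < 1e−5, well below the 2-decimal
reporting precision. Starting values come from an ordinary baseline
logistic fit (statsmodels) with a small positive initial slope.

**Profile-likelihood CIs.** Bounds sit where the profile deviance exceeds
its minimum by χ²₁(0.95) = 3.841, located by bracketing outward in Wald-SE
steps (initial half-width 20 SE, expanded up to 16-fold; a side that never
crosses is reported as an open ±inf bound) and Brent root finding with
parameter tolerance 1e−4·SE. Nuisance parameters are re-maximized at every
probe, warm-started from the neighbouring probe; probe evaluations are
memoized so the root finder sees a deterministic function.

**MCML.** The objective is `log[(1/M)·Σ_j exp(ℓ_j)]` with ℓ_j the
*full-cohort* log-likelihood under realization column j, computed by
log-sum-exp; averaging at cohort level (not per subject) respects the
between-subject correlation of realizations. Gradients are the
softmax-weighted average of per-column gradients. Profile CIs use the same
objective. When one column dominates the average by more than 50 log units
a warning reports the effective number of realizations — with purely
unshared error and large N this degeneracy is the norm rather than the
exception, and MCML then behaves like a best-column fit; it is the shared
error component that likelihood averaging genuinely propagates into the
interval width. A per-subject averaging variant
(`subject_averaged_loglik`) is exposed for diagnosis only.

**Bayesian MCMC.** Metropolis-within-Gibbs over the continuous parameters
(componentwise adaptive random walks, Normal(0, 10²) priors by default,
exact likelihood with −inf outside the support) and the realization index
(multinomial with the Dirichlet(1) hyperprior collapsed out, hence
symmetric; updated by uniform-proposal Metropolis for large M, exact Gibbs
for M ≤ 50). Proposal scales adapt only during burn-in (target acceptance
0.2–0.4, updated every 100 sweeps) and are frozen afterwards to preserve
detailed balance. Chains start overdispersed around the
regression-calibration MLE. Reported are marginal 1-D KDE modes (Gaussian
KDE, 512-point grid) — "maximum posterior" is read as the marginal mode,
the joint mode being ill-defined across the discrete index — 95% equal-tail
credible intervals from pooled draws, classic Gelman–Rubin PSRF
(`sqrt(((n−1)/n·W + B/n)/W)`), and DIC = D̄ + p_D with
p_D = D̄ − D(θ̄), where the plug-in point uses posterior means of the
continuous parameters and the *modal* realization column (a mean of an
unordered index is undefined).

## Simulation experiment design

The replicate experiments behind the acceptance checks use reduced problem
sizes chosen as the package's own simulation design: cohorts of
1,200–11,732 subjects and 2–100 realizations instead of the study's
11,732 × 1,000.

Two designs deserve explanation:

- *Attenuation/correction* (N = 4,000, unshared classical GSD 1.76,
  unit-mean factors, true α = 1.5): the baseline is calibrated to an
  expected 200 cases rather than the study's ~0.75% prevalence. α̂'s
  sampling distribution is bounded below near zero and unbounded above; at
  ~30 cases its right skew inflates the replicate mean by ~30% and masks
  the attenuation signal entirely. The experiment tests the error
  mechanism, so it uses a baseline informative enough for the mean to be
  meaningful.
- *Interval widening* (regression calibration vs MCML): the error budget is
  split into a shared transport factor (GSD 1.35) and an unshared
  measurement factor (GSD 1.6), total per-subject GSD ≈ 1.76. A shared
  dose-scale error is confounded with α, and only full-likelihood averaging
  over cohort realizations carries it into the interval; with purely
  unshared error the widening is below Monte Carlo resolution at feasible
  replicate counts (and MCML degenerates to a best-column fit, see above).

## Numerical choices and degenerate inputs

- Optimizer: L-BFGS-B, ftol 1e−13, projected-gradient tol 1e−9; restarts
  as above. Ties in the likelihood are broken by whichever optimum is
  found first at equal value (column permutations of the realization
  matrix leave the MCML objective exactly invariant).
- Deviance is −2·log-likelihood; df is subjects minus parameters; the LRT
  clips statistics in (−1e−6, 0) to zero and treats anything more negative
  as an optimizer failure.
- A cohort in which all cases sit at zero dose drives α̂ to its boundary;
  the fit is reported with `converged=False` rather than crashing.
- Subjects with a zero realized dose have undefined GSD: flagged, reported
  as NaN, excluded from GSD summaries with a warning.
- `realization_summary` requires M ≥ 2; `summarize_posterior` requires
  ≥ 1,000 pooled draws; PSRF requires ≥ 2 chains and returns sentinel
  values (with a warning) under zero within-chain variance.

## Known limitations

- The dosimetry error model is multiplicative and truth-anchored (or
  posterior-anchored via `posterior_dose_realizations`); it does not
  propagate uncertainty through an actual transport model, and shared
  errors enter as scale factors rather than through physically distinct
  pathways.
- Regression calibration inherits its usual approximation in nonlinear
  models; with strong shrinkage (low dose-measurement reliability) it can
  overcorrect the slope of convex dose-response shapes.
- The MCML effective-realization degeneracy under unshared-dominated error
  budgets means its intervals should not be read as fully propagating
  unshared uncertainty; the Bayesian route is preferable there.
- DIC with a discrete latent index has no unique definition; the modal
  column plug-in is one defensible choice and DIC values should be
  compared only across models fitted with the same convention.
- Age-category baselines use quartile bins by default; fitted baseline
  coefficients are not comparable across cohorts unless cutpoints are
  fixed explicitly.
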