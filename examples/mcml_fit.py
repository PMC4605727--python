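"""Monte Carlo maximum likelihood over cohort dose realizations.

With a shared dosimetry error (a cohort-wide transport factor drawn once
per realization) the dose scale itself is uncertain.  Regression
calibration's plug-in mean averages that component away; MCML maximizes the
likelihood averaged over whole-cohort realizations and therefore carries the
shared uncertainty into the profile interval.
"""

from doserisk import (ErrorParameterSpec, ModelSpec, SimulationConfig,
                      fit_mcml, mcml_loglik, profile_ci,
                      regression_calibration_fit, simulate_cohort)

specs = [
    ErrorParameterSpec("shared_transport", "shared", "lognormal",
                       {"gsd": 1.35, "center": "mean"}),
    ErrorParameterSpec("measurement", "unshared", "lognormal",
                       {"gsd": 1.6, "center": "mean"}),
]
cfg = SimulationConfig(n_subjects=3000, n_realizations=50, seed=33,
                       target_cases=150, error_specs=specs)
cohort, true_doses, matrix = simulate_cohort(cfg)

spec = ModelSpec(dose_response="linear")
rc = regression_calibration_fit(cohort, matrix, spec)
mc = fit_mcml(cohort, matrix, spec)

lo_rc, hi_rc = profile_ci(rc, "alpha")
lo_mc, hi_mc = profile_ci(mc, "alpha")
print(f"regression calibration: alpha = {rc.estimate('alpha'):.2f} "
      f"(95% CI {lo_rc:.2f}, {hi_rc:.2f}), width {hi_rc - lo_rc:.2f}")
print(f"MCML:                   alpha = {mc.estimate('alpha'):.2f} "
      f"(95% CI {lo_mc:.2f}, {hi_mc:.2f}), width {hi_mc - lo_mc:.2f}")
print(f"\nMCML log-mean-likelihood at its optimum: {mc.loglik:.3f}")
print(f"(equals log[(1/M) sum_j exp(l_j)] with full-cohort l_j per "
      f"realization column,\nhere M = {matrix.n_realizations}; verified "
      f"independently: {mcml_loglik(mc.estimates, cohort, matrix):.3f})")
print("\nThe MCML interval is typically the wider one: it integrates the "
      "shared\ndose-scale uncertainty that the plug-in mean cannot see.")
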