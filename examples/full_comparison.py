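"""The full comparative analysis: one table, four estimation routes.

Simulates a cohort with dose-realization uncertainty, applies the exclusion
stage, fits the dose-free and linear EOR models by every route (unadjusted
central doses, regression calibration, MCML, Bayesian MCMC) and renders the
comparative report: fit statistic (deviance, or DIC for the Bayesian rows),
LRT p-values down the nesting ladder, alpha with 95% intervals, and the
percent change of alpha relative to the unadjusted fit.
"""

from doserisk import AnalysisConfig, SimulationConfig, render_table, run_pipeline

config = AnalysisConfig(
    simulation=SimulationConfig(n_subjects=3000, n_realizations=25, seed=77,
                                target_cases=150),
    model_specs=("null", "aD"),
    methods=("unadjusted", "regression_calibration", "mcml", "mcmc"),
    mcmc_chains=3, mcmc_burn_in=1000, mcmc_draws=6000,
    seed=77,
)
report = run_pipeline(config)
print(render_table(report, "markdown"))
print("Rows share one simulated data set; differences between methods "
      "reflect how each\nhandles the dose-realization uncertainty, not "
      "sampling noise.")
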