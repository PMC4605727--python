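"""Correlated cohort dose realizations from shared and unshared errors.

Generates 1,000 stochastic dose sets for a small cohort with the default
error budget (two shared transport factors, three unshared measurement
factors with per-subject heterogeneous uncertainty) and summarizes the
per-subject geometric standard deviations, which emulate the 1.3-5 range
with mean near 1.76 reported for stochastic thyroid dosimetry.
"""

import numpy as np

from doserisk import (default_error_specs, dump_error_specs,
                      generate_realizations, realization_summary)

rng = np.random.default_rng(0)
n = 500
true_doses = rng.lognormal(np.log(0.68) - 0.5 * 1.6**2, 1.6, n)  # Gy

specs = default_error_specs(n, seed=0)
print("error budget (YAML):")
print(dump_error_specs(specs)[:400], "...\n")

matrix = generate_realizations(true_doses, specs, M=1000, seed=42)
summary = realization_summary(matrix)

print(f"cohort mean of per-subject mean doses: {summary.cohort_mean:.3f} Gy")
print(f"per-subject GSD: mean {summary.mean_gsd:.3f}, "
      f"geometric mean {summary.geometric_mean_gsd:.3f}, "
      f"range {summary.per_subject['gsd'].min():.2f}-"
      f"{summary.per_subject['gsd'].max():.2f}")

# shared draws make subjects move together within a column
r = matrix.doses / true_doses[:, None]
col_corr = np.corrcoef(np.log(r[0]), np.log(r[1]))[0, 1]
print(f"\nbetween-subject correlation of log error factors across columns: "
      f"{col_corr:.3f}")
print("(positive because the two shared transport factors are drawn once "
      "per column)")
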