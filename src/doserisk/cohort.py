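"""Synthetic screening-cohort generation.

Emulates the structure of a Chernobyl-type thyroid screening prevalence
cohort: subjects exposed as children or adolescents (age at exposure
0-17.99 years at the accident), screened 10-18 years later, with lognormal
true thyroid doses and prevalent-case outcomes drawn from the EOR logistic
model at the true dose.  Default scale: about 11,611 analysable subjects and
an expected 87 prevalent cases, a cohort-mean true dose of 0.68 Gy, and
M = 1,000 correlated cohort dose realizations.

Covariates are drawn independently of dose by default (the joint
distribution in the real cohort is unknown); a ``dose_covariate_link`` hook
allows configurable dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dosimetry import (DoseRealizationMatrix, ErrorParameterSpec,
                        default_error_specs, generate_realizations)
from .risk import RiskParameters, excess_odds_ratio

__all__ = [
    "SimulationConfig",
    "DEFAULT_TRUTH",
    "DEFAULT_AGE_CUTPOINTS",
    "EXCLUSION_RULES",
    "simulate_cohort",
    "apply_exclusions",
    "calibrate_intercept",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Exclusion rules in application order, with default simulation rates taken
#: from the exclusion tallies of the Belarus screening study
#: (20 + 114 + 90 + 14 + 121 of 11,732 enrolled).
EXCLUSION_RULES = {
    "bad_id": 20 / 11732,
    "ineligible_age": 114 / 11732,
    "poor_measurement": 90 / 11732,
    "not_interviewed": 14 / 11732,
    "prior_disease": 121 / 11732,
}

DEFAULT_OBLASTS = ("gomel", "minsk", "mogilev")

#: Screening-age category boundaries (years) used by the generating truth.
DEFAULT_AGE_CUTPOINTS = (18.0, 22.0, 26.0)

#: Default generating truth: linear EOR of 1.5 per Gy, modest baseline
#: covariate effects (female-dominant baseline thyroid cancer risk), and an
#: intercept placeholder that :func:`simulate_cohort` re-calibrates so that
#: the expected case count matches ``target_cases``.
DEFAULT_TRUTH = RiskParameters(
    beta0=-5.0,
    beta_sex=-0.7,
    beta_oblast=np.array([0.15, -0.1]),
    beta_age=np.array([0.2, 0.35, 0.5]),
    alpha=1.5,
)


@dataclass
class SimulationConfig:
    """Everything needed to simulate one cohort with dose realizations.

    ``dose_mean`` (Gy) and ``dose_sigma_log`` set the lognormal true-dose
    distribution (defaults: mean 0.68 Gy, sigma_log 1.6, spanning roughly
    half a mGy to tens of Gy at cohort scale).  ``target_cases`` fixes the
    expected prevalent-case count by re-calibrating the baseline intercept;
    set it to ``None`` to use ``truth.beta0`` as given.  ``error_specs=None``
    selects the default shared/unshared lognormal error fixture.
    """

    n_subjects: int = 11611
    dose_mean: float = 0.68
    dose_sigma_log: float = 1.6
    truth: RiskParameters = field(default_factory=lambda: DEFAULT_TRUTH)
    target_cases: float | None = 87.0
    error_specs: Sequence[ErrorParameterSpec] | None = None
    n_realizations: int = 1000
    seed: int = 0
    oblasts: Sequence[str] = DEFAULT_OBLASTS
    age_cutpoints: Sequence[float] = DEFAULT_AGE_CUTPOINTS
    exclusion_rates: Mapping[str, float] | None = None
    dose_covariate_link: Callable | None = None
    group_labels: Mapping[str, Sequence] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.target_cases is not None and not self.target_cases >= 1:
            raise ValueError("expected case count must be >= 1")
        if self.dose_mean <= 0 or self.dose_sigma_log < 0:
            raise ValueError("invalid true-dose hyperparameters")


def _case_probabilities(truth: RiskParameters, cohort: pd.DataFrame,
                        doses: np.ndarray, oblasts: Sequence[str],
                        cutpoints: Sequence[float]) -> np.ndarray:
    male = (cohort["gender"].to_numpy() == "male").astype(float)
    eor = excess_odds_ratio(truth, doses,
                            e=cohort["age_at_exposure"].to_numpy(dtype=float),
                            a=cohort["age_at_screening"].to_numpy(dtype=float),
                            sex=cohort["gender"].to_numpy())
    if np.min(1.0 + eor) <= 0:
        raise ValueError("truth parameters give 1 + EOR <= 0 for some subject")
    lp = truth.beta0 + truth.beta_sex * male
    ob = cohort["oblast"].astype(str).to_numpy()
    for i, lev in enumerate(list(oblasts)[1:]):
        if i < truth.beta_oblast.size:
            lp = lp + truth.beta_oblast[i] * (ob == lev)
    a = cohort["age_at_screening"].to_numpy(dtype=float)
    cat = np.digitize(a, np.asarray(cutpoints, dtype=float))
    for k in range(1, len(cutpoints) + 1):
        if k - 1 < truth.beta_age.size:
            lp = lp + truth.beta_age[k - 1] * (cat == k)
    x = np.exp(lp) * (1.0 + eor)
    return x / (1.0 + x)


def calibrate_intercept(truth: RiskParameters, cohort: pd.DataFrame,
                        doses: np.ndarray, target_cases: float,
                        oblasts: Sequence[str], cutpoints: Sequence[float]
                        ) -> float:
    """Intercept beta0 making the expected case count equal ``target_cases``.

    Solved by root finding on the sum of case probabilities; the expected
    count is monotone increasing in the intercept, so the root is unique.
    """
    base = RiskParameters(**{**truth.__dict__})

    def expected(b0: float) -> float:
        base.beta0 = b0
        return _case_probabilities(base, cohort, doses, oblasts, cutpoints).sum()

    return brentq(lambda b0: expected(b0) - target_cases, -30.0, 10.0, xtol=1e-10)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, np.ndarray, DoseRealizationMatrix]:
    """Simulate (cohort table, true doses, dose-realization matrix).

    Covariates: age at exposure uniform on [0, 18) years, screening delay
    uniform on [10, 18] years (screening 10-18 years after exposure, centring
    screening age near 22), gender 1:1, oblasts equiprobable.  True doses are
    lognormal with the configured arithmetic mean.  Case indicators are
    Bernoulli with the EOR-logistic probability at the *true* dose.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    e = rng.uniform(0.0, 18.0, n)
    a = e + rng.uniform(10.0, 18.0, n)
    gender = np.where(rng.random(n) < 0.5, "male", "female")
    oblast = rng.choice(np.asarray(config.oblasts, dtype=object), n)
    sigma = config.dose_sigma_log
    mu = np.log(config.dose_mean) - 0.5 * sigma**2
    true_doses = np.exp(rng.normal(mu, sigma, n))

    cohort = pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "gender": gender,
        "oblast": oblast,
        "age_at_exposure": e,
        "age_at_screening": a,
    })
    if config.dose_covariate_link is not None:
        true_doses = np.asarray(
            config.dose_covariate_link(rng, cohort, true_doses), dtype=float)

    truth = RiskParameters(**{**config.truth.__dict__})
    if config.target_cases is not None:
        truth.beta0 = calibrate_intercept(truth, cohort, true_doses,
                                          config.target_cases, config.oblasts,
                                          config.age_cutpoints)
    p = _case_probabilities(truth, cohort, true_doses, config.oblasts,
                            config.age_cutpoints)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("degenerate baseline: case probability outside (0, 1)")
    cohort["is_case"] = (rng.random(n) < p).astype(int)

    rates = config.exclusion_rates
    if rates:
        for rule in EXCLUSION_RULES:
            rate = rates.get(rule, 0.0)
            cohort[f"excl_{rule}"] = (rng.random(n) < rate).astype(int)

    specs = (list(config.error_specs) if config.error_specs is not None
             else default_error_specs(n, seed=config.seed + 1))
    matrix = generate_realizations(true_doses, specs, config.n_realizations,
                                   seed=config.seed + 2,
                                   group_labels=config.group_labels)
    matrix.subject_ids = cohort["subject_id"].to_numpy()
    return cohort, true_doses, matrix


def apply_exclusions(records: pd.DataFrame,
                     rules: Sequence[str] = tuple(EXCLUSION_RULES)
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop flagged subjects; return the retained table and a per-rule tally.

    Rules are applied in order: a subject carrying several flags is counted
    under the first matching rule only, so the tally plus the retained count
    always equals the input count.  Missing flag columns count as no flag.
    """
    remaining = records.copy()
    tally: dict[str, int] = {}
    for rule in rules:
        col = f"excl_{rule}"
        if col in remaining.columns:
            flagged = remaining[col].astype(bool)
            tally[rule] = int(flagged.sum())
            remaining = remaining.loc[~flagged]
        else:
            tally[rule] = 0
    return remaining.reset_index(drop=True), tally


_COHORT_COLUMNS = ["subject_id", "gender", "oblast", "age_at_exposure",
                   "age_at_screening", "is_case"]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write the cohort as UTF-8 CSV in the documented column order
    (subject_id, gender, oblast, age_at_exposure, age_at_screening, is_case,
    then any exclusion-flag columns)."""
    extra = [c for c in cohort.columns if c not in _COHORT_COLUMNS]
    cohort[_COHORT_COLUMNS + extra].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return cohort
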