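"""Monte Carlo maximum likelihood (MCML) over cohort dose realizations.

The dose-realization matrix provides M draws of the *entire cohort* dose
vector; realizations are correlated between subjects through shared
dosimetry parameters.  MCML therefore averages the full-cohort likelihood
over realizations,

    L(params) = (1/M) * sum_j exp( l_j(params) ),

where ``l_j`` is the complete-cohort log-likelihood under realization column
j - not a product of per-subject averaged likelihoods, which would wrongly
treat realizations as independent across subjects.  The log of this average
is computed with a numerically stable log-sum-exp and maximized with the
same machinery (and profile-CI conventions) as the single-vector fits.
A per-subject averaging variant is exposed only as a labelled diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .dosimetry import DoseRealizationMatrix
from .ml import FitResult, _maximize, _wald_se, fit_ml
from .risk import CohortDesign, ModelSpec, RiskParameters, PENALTY_LOGLIK

__all__ = ["MCMLState", "mcml_loglik", "fit_mcml", "subject_averaged_loglik"]

# One column dominating the log-sum-exp by this many log units signals that
# the Monte Carlo average has effectively collapsed onto a single realization.
_DOMINANCE_GAP = 50.0


@dataclass
class MCMLState:
    """Per-realization log-likelihoods and their log-mean at one parameter
    point; ``aggregate == logsumexp(per_column) - log M`` exactly."""

    per_column: np.ndarray
    aggregate: float
    theta: np.ndarray

    @property
    def effective_realizations(self) -> float:
        """Effective number of realizations 1 / sum(w_j^2) under the
        normalized likelihood weights."""
        w = softmax(self.per_column)
        return float(1.0 / np.sum(w**2))


def _mcml_state(design: CohortDesign, theta: np.ndarray,
                dose_matrix: np.ndarray, warn_dominance: bool = False
                ) -> MCMLState:
    lvec = design.loglik_columns(theta, dose_matrix)
    agg = float(logsumexp(lvec) - np.log(lvec.size))
    state = MCMLState(per_column=lvec, aggregate=agg, theta=np.asarray(theta))
    if warn_dominance and lvec.size > 1:
        top2 = np.partition(lvec, -2)[-2:]
        if top2[1] - top2[0] > _DOMINANCE_GAP:
            warnings.warn(
                f"one realization dominates the MCML average by "
                f"{top2[1] - top2[0]:.1f} log units (effective realizations "
                f"{state.effective_realizations:.2f} of {lvec.size})",
                stacklevel=3)
    return state


def mcml_loglik(params: RiskParameters, cohort: pd.DataFrame,
                matrix: DoseRealizationMatrix) -> float:
    """log[(1/M) sum_j exp(l_j(params))] with full-cohort l_j per column.

    Columns in the penalty region contribute their penalized log-likelihood
    to the average; being many thousands of log units below any feasible
    column, they carry effectively zero weight in the log-sum-exp.
    """
    spec = ModelSpec(dose_response="linear_exponential",
                     modifiers=frozenset(("age_at_exposure", "age_at_screening",
                                          "sex")))
    design = CohortDesign(cohort, spec)
    return _mcml_state(design, design.pack(params), matrix.doses).aggregate


def _mcml_objective(design: CohortDesign, dose_matrix: np.ndarray):
    """(value, gradient) callable: grad = sum_j w_j grad l_j, with softmax
    weights w_j over the per-column log-likelihoods."""

    def obj(theta):
        lvec = design.loglik_columns(theta, dose_matrix)
        agg = logsumexp(lvec) - np.log(lvec.size)
        w = softmax(lvec)
        G = design.grad_columns(theta, dose_matrix)
        return float(agg), G @ w

    return obj


def fit_mcml(cohort: pd.DataFrame, matrix: DoseRealizationMatrix,
             spec: ModelSpec, start: RiskParameters | None = None) -> FitResult:
    """Maximize the realization-averaged likelihood; profile CIs use the same
    objective.  Warm-started from the regression-calibration fit unless
    ``start`` is given.  The reported deviance is ``-2 *`` the maximized
    log-mean-likelihood."""
    design = CohortDesign(cohort, spec)
    obj = _mcml_objective(design, matrix.doses)
    if start is not None:
        theta0 = design.pack(start)
    else:
        rc = fit_ml(cohort, matrix.subject_means(), spec, design=design)
        theta0 = rc.theta
    theta, ll, converged, n_eval = _maximize(obj, theta0)
    _mcml_state(design, theta, matrix.doses, warn_dominance=True)
    se = _wald_se(obj, theta)
    return FitResult(
        estimates=design.unpack(theta),
        deviance=-2.0 * ll,
        df=design.n - design.n_params,
        loglik=ll,
        param_names=list(design.param_names),
        theta=theta,
        wald_se=dict(zip(design.param_names, se)),
        converged=converged,
        n_evaluations=n_eval,
        method_label="mcml",
        spec=spec,
        objective=obj,
        design=design,
    )


def subject_averaged_loglik(params: RiskParameters, cohort: pd.DataFrame,
                            matrix: DoseRealizationMatrix) -> float:
    """Diagnostic variant: sum_i log[(1/M) sum_j L_i(dose_ij)].

    Averages the likelihood per subject before taking the product, which
    treats realizations as independent across subjects and ignores the
    shared-error correlation; provided for comparison only, never used for
    estimation.
    """
    spec = ModelSpec(dose_response="linear_exponential",
                     modifiers=frozenset(("age_at_exposure", "age_at_screening",
                                          "sex")))
    design = CohortDesign(cohort, spec)
    theta = design.pack(params)
    beta = theta[: design.n_baseline]
    lp = design.X @ beta
    eor, _ = design._eor(theta, matrix.doses)
    one = 1.0 + eor
    if np.min(one) <= 0:
        return PENALTY_LOGLIK
    from scipy.special import log_expit
    t = lp[:, None] + np.log(one)
    per = np.where(design.y[:, None] > 0.5, log_expit(t), log_expit(-t))
    return float(np.sum(logsumexp(per, axis=1) - np.log(matrix.n_realizations)))
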