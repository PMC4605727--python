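"""Maximum-likelihood inference for the EOR logistic model.

Fits any :class:`~doserisk.risk.ModelSpec` on a single dose vector (the
deterministic dose for the unadjusted analysis, or the per-subject mean over
realizations for regression calibration), and provides profile-likelihood
confidence intervals and likelihood-ratio tests.

The optimizer is quasi-Newton (L-BFGS-B) on the unconstrained parameter
space with analytic gradients; parameter points where ``1 + EOR <= 0`` for
any subject return a large finite penalty with a restoring slope, so the
optimum is always interior to the valid region.  On failure, up to five
jittered restarts are attempted.  Any maximizer reaching the same optimum is
equivalent for reporting purposes: the contract is the optimum, not the
path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .dosimetry import DoseRealizationMatrix
from .risk import CohortDesign, ModelSpec, RiskParameters, PENALTY_LOGLIK

__all__ = ["FitResult", "fit_ml", "profile_ci", "lrt",
           "regression_calibration_fit", "fit_report_row"]

_GRAD_TOL = 1e-5          # convergence: gradient infinity-norm threshold
_MAX_RESTARTS = 5
_PROFILE_RANGE_SE = 20.0  # initial profile search half-width in Wald SEs


@dataclass
class FitResult:
    """One fitted model row: estimates, deviance, CIs, convergence metadata."""

    estimates: RiskParameters
    deviance: float
    df: int
    loglik: float
    param_names: list
    theta: np.ndarray
    wald_se: dict
    profile_cis: dict = field(default_factory=dict)
    converged: bool = True
    n_evaluations: int = 0
    method_label: str = "unadjusted"
    spec: ModelSpec | None = field(default=None, repr=False)
    objective: Callable | None = field(default=None, repr=False)
    design: CohortDesign | None = field(default=None, repr=False)

    def estimate(self, name: str) -> float:
        return float(self.theta[self.param_names.index(name)])

    def to_json(self) -> str:
        payload = {
            "method": self.method_label,
            "model": self.spec.label() if self.spec is not None else None,
            "deviance": self.deviance,
            "df": self.df,
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_evaluations": self.n_evaluations,
            "estimates": {k: float(v) for k, v in zip(self.param_names, self.theta)},
            "wald_se": {k: float(v) for k, v in self.wald_se.items()},
            "profile_ci": {k: [float(a), float(b)]
                           for k, (a, b) in self.profile_cis.items()
                           if isinstance(k, str)},
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Generic maximizer shared with the MCML objective
# ---------------------------------------------------------------------------

def _maximize(loglik_grad: Callable, theta0: np.ndarray, rng=None,
              max_restarts: int = _MAX_RESTARTS):
    """Maximize a log-likelihood given a (value, gradient) callable."""
    n_eval = 0

    def neg(theta):
        nonlocal n_eval
        n_eval += 1
        ll, g = loglik_grad(theta)
        return -ll, -g

    best = None
    rng = np.random.default_rng(0) if rng is None else rng
    theta_start = np.asarray(theta0, dtype=float)
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(neg, theta_start, jac=True, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-13,
                                         "gtol": 1e-9})
        ll, g = loglik_grad(res.x)
        ok = np.isfinite(ll) and ll > PENALTY_LOGLIK / 2 and \
            np.max(np.abs(g)) < _GRAD_TOL
        if best is None or ll > best[1]:
            best = (res.x, ll, g, ok)
        if ok:
            break
        if attempt >= 1:
            # near the feasibility boundary the curvature explodes and
            # quasi-Newton steps stall; a derivative-free polish from the
            # best point so far escapes that regime
            nm = optimize.minimize(lambda th: -loglik_grad(th)[0], best[0],
                                   method="Nelder-Mead",
                                   options={"maxiter": 4000, "fatol": 1e-12,
                                            "xatol": 1e-10})
            ll_nm, g_nm = loglik_grad(nm.x)
            gain = ll_nm - best[1]
            if gain > 0:
                best = (nm.x, ll_nm, g_nm,
                        np.max(np.abs(g_nm)) < _GRAD_TOL)
            if gain <= 1e-9:
                break  # polish stalled: a boundary-pinned optimum
            theta_start = nm.x
        else:
            scale = np.maximum(np.abs(theta_start), 0.1)
            theta_start = best[0] + 0.3 * scale * rng.standard_normal(len(theta0))
    theta_hat, ll_hat, g_hat, converged = best
    return theta_hat, ll_hat, converged, n_eval


def _wald_se(loglik_grad: Callable, theta: np.ndarray) -> np.ndarray:
    """SEs from the inverse observed information (central-difference Hessian
    of the analytic gradient)."""
    p = len(theta)
    H = np.empty((p, p))
    h = 1e-5 * np.maximum(np.abs(theta), 1.0)
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = loglik_grad(tp)
        _, gm = loglik_grad(tm)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.where(np.diag(cov) > 0, np.diag(cov), np.nan))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def _baseline_start(design: CohortDesign) -> np.ndarray:
    """Plain logistic regression of case status on the baseline covariates."""
    import statsmodels.api as sm
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(design.y, design.X).fit(disp=0, maxiter=200)
        beta = np.asarray(fit.params, dtype=float)
        if not np.all(np.isfinite(beta)):
            raise ValueError
    except Exception:
        rate = np.clip(design.y.mean(), 1e-6, 1 - 1e-6)
        beta = np.zeros(design.n_baseline)
        beta[0] = np.log(rate / (1 - rate))
    return beta


def fit_ml(cohort: pd.DataFrame, doses, spec: ModelSpec,
           start: RiskParameters | None = None, *,
           method_label: str = "unadjusted",
           design: CohortDesign | None = None) -> FitResult:
    """Maximum-likelihood fit of ``spec`` on a single dose vector.

    Starting values come from an ordinary baseline logistic fit with a small
    positive initial dose slope, unless ``start`` is given.  ``converged``
    means the gradient infinity-norm fell below tolerance outside the
    penalty region; on persistent failure the best point found is still
    reported with ``converged=False``.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(~np.isfinite(doses)) or np.any(doses < 0):
        raise ValueError("doses must be finite and non-negative")
    if design is None:
        design = CohortDesign(cohort, spec)

    def obj(theta):
        return design.loglik_grad(theta, doses)

    if start is not None:
        theta0 = design.pack(start)
    else:
        theta0 = np.zeros(design.n_params)
        theta0[: design.n_baseline] = _baseline_start(design)
        if "alpha" in design.param_names:
            theta0[design.param_names.index("alpha")] = 0.1

    theta, ll, converged, n_eval = _maximize(obj, theta0)
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
        method_label=method_label,
        spec=spec,
        objective=obj,
        design=design,
    )


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _profile_loglik(objective: Callable, theta_hat: np.ndarray, index: int,
                    value: float, warm: dict) -> float:
    """Max log-likelihood with parameter ``index`` fixed at ``value``."""
    free = [j for j in range(len(theta_hat)) if j != index]
    start = warm.get("theta", theta_hat)[free]

    def reduced(th_free):
        full = np.empty(len(theta_hat))
        full[free] = th_free
        full[index] = value
        ll, g = objective(full)
        return ll, g[free]

    if len(free) == 0:
        full = np.array([value])
        return objective(full)[0]
    th, ll, _, _ = _maximize(reduced, start, max_restarts=1)
    full = np.empty(len(theta_hat))
    full[free] = th
    full[index] = value
    warm["theta"] = full
    return ll


def profile_ci(fit: FitResult, parameter: str, level: float = 0.95
               ) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one parameter.

    Bounds are where the profile deviance exceeds its minimum by the
    chi-square(1) quantile (3.841 at 95%), located by bracketing in Wald-SE
    steps (initial range +/-20 SE, expanded up to 16-fold) and root finding;
    a side that never crosses within the expanded range is reported as an
    open bound (+/-inf).  Nuisance parameters are re-maximized at each probe.
    The result is cached on ``fit.profile_cis``.
    """
    if fit.objective is None:
        raise ValueError("fit does not carry its objective; cannot profile")
    if not fit.converged:
        warnings.warn("profiling a fit that did not converge", stacklevel=2)
    key = (parameter, level)
    if key in fit.profile_cis:
        return fit.profile_cis[key]
    idx = fit.param_names.index(parameter)
    est = fit.theta[idx]
    se = fit.wald_se.get(parameter, np.nan)
    step = se if np.isfinite(se) and se > 0 else max(abs(est), 0.5)
    crit = chi2.ppf(level, 1)
    target = -2.0 * fit.loglik + crit

    bounds = []
    for sign in (-1.0, +1.0):
        warm: dict = {}
        cache: dict = {}

        def g(v):
            # memoized: the profile value at a probe must not depend on the
            # warm-start state accumulated by later probes
            if v not in cache:
                cache[v] = -2.0 * _profile_loglik(fit.objective, fit.theta,
                                                  idx, v, warm) - target
            return cache[v]

        lo_v, lo_g = est, -crit
        bound = sign * np.inf
        k = 1.0
        while k <= 16 * _PROFILE_RANGE_SE:
            v = est + sign * k * step
            gv = g(v)
            if np.isfinite(gv) and gv > 0:
                a, b = (v, lo_v) if sign < 0 else (lo_v, v)
                bound = optimize.brentq(g, a, b, xtol=1e-4 * step)
                break
            if np.isfinite(gv):
                lo_v = v
            k *= 2.0
        else:
            warnings.warn(f"profile for {parameter} did not cross within "
                          f"{16 * _PROFILE_RANGE_SE:.0f} SEs: open bound",
                          stacklevel=2)
        bounds.append(bound)
    ci = (bounds[0], bounds[1])
    fit.profile_cis[key] = ci
    fit.profile_cis[parameter] = ci  # convenience alias at the default level
    return ci


def lrt(fit_nested: FitResult, fit_full: FitResult
        ) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a full model.

    Returns (statistic, df, p).  The statistic is the deviance difference;
    small negative values (optimizer noise below 1e-6) are clipped to zero,
    larger ones raise, since they indicate a failed maximization.
    """
    df = len(fit_full.param_names) - len(fit_nested.param_names)
    if df <= 0:
        raise ValueError("full model must have more parameters than nested model")
    stat = fit_nested.deviance - fit_full.deviance
    if stat < -1e-6:
        raise RuntimeError(f"negative LRT statistic {stat:g}: optimizer failure")
    stat = max(stat, 0.0)
    return stat, df, float(chi2.sf(stat, df))


def regression_calibration_fit(cohort: pd.DataFrame,
                               matrix: DoseRealizationMatrix,
                               spec: ModelSpec, **kwargs) -> FitResult:
    """Regression calibration: plug in the per-subject arithmetic mean of the
    dose realizations (the expected true dose given all dosimetry
    information) and fit by maximum likelihood."""
    return fit_ml(cohort, matrix.subject_means(), spec,
                  method_label="regression_calibration", **kwargs)


def fit_report_row(fit: FitResult, ci_level: float = 0.95,
                   profile_params: Sequence[str] | None = None) -> dict:
    """Flatten a fit into a Table-style report row (dict)."""
    if profile_params is None:
        profile_params = [p for p in ("alpha", "gamma", "kappa", "tau", "eta")
                          if p in fit.param_names]
    row = {
        "method": fit.method_label,
        "model": fit.spec.label() if fit.spec is not None else "",
        "fit_stat": fit.deviance,
        "df": fit.df,
        "converged": fit.converged,
    }
    for p in ("alpha", "gamma", "kappa", "tau", "eta"):
        if p in fit.param_names:
            row[p] = fit.estimate(p)
            if p in profile_params:
                lo, hi = profile_ci(fit, p, ci_level)
                row[f"{p}_lo"], row[f"{p}_hi"] = lo, hi
        else:
            row[p] = np.nan
    return row
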