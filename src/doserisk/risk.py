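"""Excess-odds-ratio (EOR) logistic risk model for binary prevalence outcomes.

The probability that subject *i* (age at screening ``a``, gender ``s``, age at
exposure ``e``, true thyroid dose ``D`` in Gy) is a prevalent case is

.. math::

    p_i = \\frac{x_i}{1 + x_i}, \\qquad
    x_i = \\exp\\Big[\\beta_0 + \\beta_s 1_{s=male}
          + \\sum_m \\beta^o_m 1_{oblast=m} + \\sum_k \\beta^a_k 1_{a \\in A_k}\\Big]
          \\cdot \\big(1 + \\alpha D e^{\\gamma D + \\kappa(e-8) + \\tau(a-22)
          + \\eta 1_{s=male}}\\big)

so the odds ratio at dose ``D`` relative to zero dose is ``1 + EOR(D)`` with
``EOR(D) = alpha * D * exp(gamma*D + kappa*(e-8) + tau*(a-22) + eta*male)``.
``alpha`` is the excess odds ratio per Gy; ``gamma`` allows curvature;
``kappa``, ``tau`` and ``eta`` are log-linear effect modifiers.  The ages are
centred at 8 years (exposure) and 22 years (screening), roughly the cohort
means, which decouples the modifiers from the main dose slope.

The model is only well defined where ``1 + EOR > 0`` for every subject in the
data.  Outside that region the log-likelihood is replaced by a large finite
penalty with a restoring slope so that unconstrained optimizers are pushed
back into the valid region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

__all__ = [
    "RiskParameters",
    "ModelSpec",
    "parse_model_label",
    "excess_odds_ratio",
    "case_probability",
    "log_likelihood",
    "PENALTY_LOGLIK",
]

# Centring constants for the effect-modifier terms (years).
EXPOSURE_AGE_CENTER = 8.0
SCREENING_AGE_CENTER = 22.0

# Outside the valid region (1 + EOR <= 0 for some subject) the likelihood is
# continued by clipping 1 + EOR at a small floor inside the log and adding a
# linear restoring penalty: large but finite, continuous, and sloped back
# towards feasibility, so quasi-Newton optimizers recover instead of choking
# on a cliff.  PENALTY_LOGLIK is the guaranteed lower bound of any penalized
# value (used as a sentinel scale).
PENALTY_LOGLIK = -1.0e8
_PENALTY_SLOPE = 1.0e4
_EOR_FLOOR = 1.0e-6

MODIFIERS = ("age_at_exposure", "age_at_screening", "sex")
BASELINE_COVARIATES = ("sex", "oblast", "age")


@dataclass
class RiskParameters:
    """Baseline and dose-response parameters of the EOR logistic model.

    ``beta_oblast`` holds one coefficient per non-reference oblast (reference:
    lexicographically first label) and ``beta_age`` one per non-reference
    screening-age category (reference: lowest category).
    """

    beta0: float = 0.0
    beta_sex: float = 0.0
    beta_oblast: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_age: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha: float = 0.0
    gamma: float = 0.0
    kappa: float = 0.0
    tau: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        self.beta_oblast = np.atleast_1d(np.asarray(self.beta_oblast, dtype=float))
        self.beta_age = np.atleast_1d(np.asarray(self.beta_age, dtype=float))
        if self.beta_oblast.size == 0:
            self.beta_oblast = np.zeros(0)
        if self.beta_age.size == 0:
            self.beta_age = np.zeros(0)
        for name in ("beta0", "beta_sex", "alpha", "gamma", "kappa", "tau", "eta"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for {name}")
            setattr(self, name, v)


@dataclass(frozen=True)
class ModelSpec:
    """Which dose-response shape, effect modifiers and baseline terms to fit.

    ``dose_response``: ``"null"`` (no dose term), ``"linear"`` (alpha*D) or
    ``"linear_exponential"`` (alpha*D*exp(gamma*D)).  ``modifiers`` is a subset
    of :data:`MODIFIERS` and requires a non-null dose response.
    ``age_category_cutpoints`` (years of age at screening) default to cohort
    quartiles when the design is built.  ``baseline`` selects which covariates
    enter the baseline odds (the intercept is always present).
    """

    dose_response: str = "linear"
    modifiers: frozenset = frozenset()
    age_category_cutpoints: tuple | None = None
    baseline: frozenset = frozenset(BASELINE_COVARIATES)

    def __post_init__(self) -> None:
        if self.dose_response not in ("null", "linear", "linear_exponential"):
            raise ValueError(f"unknown dose_response {self.dose_response!r}")
        object.__setattr__(self, "modifiers", frozenset(self.modifiers))
        object.__setattr__(self, "baseline", frozenset(self.baseline))
        if not self.modifiers <= set(MODIFIERS):
            raise ValueError(f"unknown modifiers {set(self.modifiers) - set(MODIFIERS)}")
        if not self.baseline <= set(BASELINE_COVARIATES):
            raise ValueError("unknown baseline covariates")
        if self.dose_response == "null" and self.modifiers:
            raise ValueError("effect modifiers require a non-null dose response")
        if self.age_category_cutpoints is not None:
            cp = tuple(float(c) for c in self.age_category_cutpoints)
            if any(b <= a for a, b in zip(cp, cp[1:])):
                raise ValueError("age category cutpoints must be strictly increasing")
            object.__setattr__(self, "age_category_cutpoints", cp)

    @property
    def has_alpha(self) -> bool:
        return self.dose_response != "null"

    @property
    def has_gamma(self) -> bool:
        return self.dose_response == "linear_exponential"

    def label(self) -> str:
        if self.dose_response == "null":
            return "null"
        if self.dose_response == "linear" and not self.modifiers:
            return "aD"
        parts = []
        if self.has_gamma:
            parts.append("gD")
        if "age_at_exposure" in self.modifiers:
            parts.append("k(e-8)")
        if "age_at_screening" in self.modifiers:
            parts.append("t(a-22)")
        if "sex" in self.modifiers:
            parts.append("s")
        return "aD*exp(" + "+".join(parts) + ")" if parts else "aD"


_LABEL_TOKENS = {
    "gD": "gamma",
    "k(e-8)": "age_at_exposure",
    "t(a-22)": "age_at_screening",
    "s": "sex",
}


def parse_model_label(label: str) -> ModelSpec:
    """Parse a compact dose-response label such as ``"aD*exp(gD+k(e-8))"``.

    Supported: ``"null"``, ``"aD"``, and ``"aD*exp(...)"`` where the
    exponent is a ``+``-joined subset of ``gD``, ``k(e-8)``, ``t(a-22)``,
    ``s`` (male indicator).
    """
    s = label.replace(" ", "")
    if s == "null":
        return ModelSpec(dose_response="null")
    if s == "aD":
        return ModelSpec(dose_response="linear")
    m = re.fullmatch(r"aD\*exp\((.+)\)", s)
    if not m:
        raise ValueError(f"cannot parse model label {label!r}")
    tokens = re.findall(r"gD|k\(e-8\)|t\(a-22\)|s", m.group(1))
    if "+".join(tokens) != m.group(1):
        raise ValueError(f"cannot parse model label {label!r}")
    has_gamma = "gD" in tokens
    modifiers = frozenset(_LABEL_TOKENS[t] for t in tokens if t != "gD")
    return ModelSpec(
        dose_response="linear_exponential" if has_gamma else "linear",
        modifiers=modifiers,
    )


# ---------------------------------------------------------------------------
# Design / parameter layout
# ---------------------------------------------------------------------------

def _male_indicator(gender: Iterable) -> np.ndarray:
    g = np.asarray(gender)
    if g.dtype.kind in "biuf":
        return g.astype(float)
    out = np.where(g == "male", 1.0, np.where(g == "female", 0.0, np.nan))
    if np.isnan(out).any():
        raise ValueError("gender must be 'male' or 'female'")
    return out


class CohortDesign:
    """Pre-computed design arrays for one cohort and one :class:`ModelSpec`."""

    def __init__(self, cohort: pd.DataFrame, spec: ModelSpec,
                 oblast_levels: Sequence | None = None,
                 age_cutpoints: Sequence[float] | None = None):
        self.spec = spec
        self.n = len(cohort)
        self.y = cohort["is_case"].to_numpy(dtype=float)
        self.male = _male_indicator(cohort["gender"])
        self.e_c = cohort["age_at_exposure"].to_numpy(dtype=float) - EXPOSURE_AGE_CENTER
        self.a_c = cohort["age_at_screening"].to_numpy(dtype=float) - SCREENING_AGE_CENTER

        cols = [np.ones(self.n)]
        names = ["beta0"]
        if "sex" in spec.baseline:
            cols.append(self.male)
            names.append("beta_sex")
        self.oblast_levels: tuple = ()
        if "oblast" in spec.baseline:
            levels = (tuple(oblast_levels) if oblast_levels is not None
                      else tuple(sorted(pd.unique(cohort["oblast"]).astype(str))))
            self.oblast_levels = levels
            ob = cohort["oblast"].astype(str).to_numpy()
            unknown = set(ob) - set(levels)
            if unknown:
                raise ValueError(f"oblast labels not in levels: {unknown}")
            for lev in levels[1:]:
                cols.append((ob == lev).astype(float))
                names.append(f"beta_oblast_{lev}")
        self.age_cutpoints: tuple = ()
        if "age" in spec.baseline:
            if age_cutpoints is not None:
                cp = tuple(float(c) for c in age_cutpoints)
            elif spec.age_category_cutpoints is not None:
                cp = spec.age_category_cutpoints
            else:
                a = cohort["age_at_screening"].to_numpy(dtype=float)
                cp = tuple(np.unique(np.quantile(a, [0.25, 0.5, 0.75])))
            self.age_cutpoints = cp
            a = cohort["age_at_screening"].to_numpy(dtype=float)
            cat = np.digitize(a, cp)  # 0..len(cp)
            for k in range(1, len(cp) + 1):
                cols.append((cat == k).astype(float))
                names.append(f"beta_age_{k}")
        self.X = np.column_stack(cols)
        self.baseline_names = names
        self.n_baseline = len(names)

        dose_names = []
        if spec.has_alpha:
            dose_names.append("alpha")
        if spec.has_gamma:
            dose_names.append("gamma")
        if "age_at_exposure" in spec.modifiers:
            dose_names.append("kappa")
        if "age_at_screening" in spec.modifiers:
            dose_names.append("tau")
        if "sex" in spec.modifiers:
            dose_names.append("eta")
        self.dose_names = dose_names
        self.param_names = names + dose_names
        self.n_params = len(self.param_names)

    # -- packing ------------------------------------------------------------
    def pack(self, params: RiskParameters) -> np.ndarray:
        theta = []
        for name in self.param_names:
            if name.startswith("beta_oblast_"):
                idx = self.oblast_levels[1:].index(name[len("beta_oblast_"):])
                theta.append(params.beta_oblast[idx] if idx < params.beta_oblast.size else 0.0)
            elif name.startswith("beta_age_"):
                idx = int(name[len("beta_age_"):]) - 1
                theta.append(params.beta_age[idx] if idx < params.beta_age.size else 0.0)
            else:
                theta.append(getattr(params, name))
        return np.asarray(theta, dtype=float)

    def unpack(self, theta: np.ndarray) -> RiskParameters:
        d = dict(zip(self.param_names, theta))
        n_ob = max(len(self.oblast_levels) - 1, 0)
        n_age = len(self.age_cutpoints)
        return RiskParameters(
            beta0=d.get("beta0", 0.0),
            beta_sex=d.get("beta_sex", 0.0),
            beta_oblast=np.array([d.get(f"beta_oblast_{lev}", 0.0)
                                  for lev in self.oblast_levels[1:]]) if n_ob else np.zeros(0),
            beta_age=np.array([d.get(f"beta_age_{k}", 0.0)
                               for k in range(1, n_age + 1)]) if n_age else np.zeros(0),
            alpha=d.get("alpha", 0.0),
            gamma=d.get("gamma", 0.0),
            kappa=d.get("kappa", 0.0),
            tau=d.get("tau", 0.0),
            eta=d.get("eta", 0.0),
        )

    # -- likelihood engine ---------------------------------------------------
    def _split(self, theta: np.ndarray):
        beta = theta[: self.n_baseline]
        d = dict(zip(self.dose_names, theta[self.n_baseline:]))
        return beta, d.get("alpha", 0.0), d.get("gamma", 0.0), d.get("kappa", 0.0), \
            d.get("tau", 0.0), d.get("eta", 0.0)

    def _eor(self, theta: np.ndarray, doses: np.ndarray):
        """Return (EOR, exp(G)*D) with broadcasting over realization columns."""
        _, alpha, gamma, kappa, tau, eta = self._split(theta)
        mod = kappa * self.e_c + tau * self.a_c + eta * self.male
        if doses.ndim == 2:
            mod = mod[:, None]
        deg = doses * np.exp(gamma * doses + mod)
        return alpha * deg, deg

    def loglik(self, theta: np.ndarray, doses: np.ndarray) -> float:
        ll, _ = self.loglik_grad(theta, doses, need_grad=False)
        return ll

    def loglik_strict(self, theta: np.ndarray, doses: np.ndarray) -> float:
        """Exact log-likelihood, ``-inf`` outside the support.

        Used by the samplers, where an infeasible point must be rejected
        outright rather than penalized.
        """
        beta, *_ = self._split(theta)
        eor, _ = self._eor(theta, doses)
        one = 1.0 + eor
        if np.min(one) <= 0.0:
            return float("-inf")
        t = self.X @ beta + np.log(one)
        return float(self.y @ log_expit(t) + (1.0 - self.y) @ log_expit(-t))

    def feasible(self, theta: np.ndarray, doses: np.ndarray) -> bool:
        """Whether 1 + EOR > floor for every subject (probability well
        defined without penalization)."""
        eor, _ = self._eor(theta, doses)
        return bool(np.min(1.0 + eor) > _EOR_FLOOR)

    def loglik_grad(self, theta: np.ndarray, doses: np.ndarray, need_grad: bool = True):
        """Penalized log-likelihood and analytic gradient on one dose vector.

        In the valid region this is the exact Bernoulli log-likelihood;
        where 1 + EOR dips below the floor it is continued by clipping
        inside the log and subtracting a linear restoring penalty.
        """
        beta, alpha, gamma, kappa, tau, eta = self._split(theta)
        lp = self.X @ beta
        eor, deg = self._eor(theta, doses)
        one_raw = 1.0 + eor
        viol = np.maximum(_EOR_FLOOR - one_raw, 0.0)
        clipped = viol > 0
        one = np.maximum(one_raw, _EOR_FLOOR)
        t = lp + np.log(one)
        ll = float(self.y @ log_expit(t) + (1.0 - self.y) @ log_expit(-t)
                   - _PENALTY_SLOPE * viol.sum())
        ll = max(ll, PENALTY_LOGLIK)
        if not need_grad:
            return ll, None
        r = self.y - expit(t)
        g = np.empty(self.n_params)
        g[: self.n_baseline] = self.X.T @ r
        # dose-term gradient: likelihood part where not clipped, restoring
        # penalty part (slope * d(1+EOR)/dtheta) where clipped
        ratio = np.where(clipped, 0.0, r / one)
        pen = np.where(clipped, _PENALTY_SLOPE, 0.0)
        for j, name in enumerate(self.dose_names, start=self.n_baseline):
            if name == "alpha":
                fac = deg
            elif name == "gamma":
                fac = eor * doses
            elif name == "kappa":
                fac = eor * self.e_c
            elif name == "tau":
                fac = eor * self.a_c
            elif name == "eta":
                fac = eor * self.male
            g[j] = ratio @ fac + pen @ fac
        return ll, g

    def loglik_columns(self, theta: np.ndarray, dose_matrix: np.ndarray) -> np.ndarray:
        """Full-cohort (penalized) log-likelihood under every realization
        column (length M)."""
        beta, *_ = self._split(theta)
        lp = self.X @ beta
        eor, _ = self._eor(theta, dose_matrix)
        one_raw = 1.0 + eor
        viol = np.maximum(_EOR_FLOOR - one_raw, 0.0)
        one = np.maximum(one_raw, _EOR_FLOOR)
        t = lp[:, None] + np.log(one)
        out = self.y @ log_expit(t) + (1.0 - self.y) @ log_expit(-t) \
            - _PENALTY_SLOPE * viol.sum(axis=0)
        return np.maximum(out, PENALTY_LOGLIK)

    def grad_columns(self, theta: np.ndarray, dose_matrix: np.ndarray) -> np.ndarray:
        """Per-column gradients of :meth:`loglik_columns`, shape (n_params, M)."""
        beta, *_ = self._split(theta)
        lp = self.X @ beta
        eor, deg = self._eor(theta, dose_matrix)
        one_raw = 1.0 + eor
        clipped = one_raw < _EOR_FLOOR
        one = np.maximum(one_raw, _EOR_FLOOR)
        t = lp[:, None] + np.log(one)
        r = self.y[:, None] - expit(t)
        M = dose_matrix.shape[1]
        G = np.zeros((self.n_params, M))
        G[: self.n_baseline] = self.X.T @ r
        ratio = np.where(clipped, 0.0, r / one)
        pen = np.where(clipped, _PENALTY_SLOPE, 0.0)
        for j, name in enumerate(self.dose_names, start=self.n_baseline):
            if name == "alpha":
                fac = deg
            elif name == "gamma":
                fac = eor * dose_matrix
            elif name == "kappa":
                fac = eor * self.e_c[:, None]
            elif name == "tau":
                fac = eor * self.a_c[:, None]
            elif name == "eta":
                fac = eor * self.male[:, None]
            G[j] = (ratio * fac).sum(axis=0) + (pen * fac).sum(axis=0)
        return G


# ---------------------------------------------------------------------------
# Public scalar/vector operations
# ---------------------------------------------------------------------------

def excess_odds_ratio(params: RiskParameters, dose, e=EXPOSURE_AGE_CENTER,
                      a=SCREENING_AGE_CENTER, sex="female"):
    """EOR(D) = alpha*D*exp(gamma*D + kappa*(e-8) + tau*(a-22) + eta*1[male]).

    Vectorized over ``dose`` (Gy); ``e``/``a`` in years.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    male = _male_indicator(np.asarray(sex)) if not np.isscalar(sex) else \
        _male_indicator(np.asarray([sex]))[0]
    g = (params.gamma * dose
         + params.kappa * (np.asarray(e, dtype=float) - EXPOSURE_AGE_CENTER)
         + params.tau * (np.asarray(a, dtype=float) - SCREENING_AGE_CENTER)
         + params.eta * male)
    out = params.alpha * dose * np.exp(g)
    return float(out) if out.ndim == 0 else out


def _baseline_lp(params: RiskParameters, subject: Mapping,
                 oblast_levels: Sequence | None, age_cutpoints: Sequence | None) -> float:
    lp = params.beta0
    lp += params.beta_sex * _male_indicator(np.asarray([subject["gender"]]))[0]
    if params.beta_oblast.size:
        if oblast_levels is None:
            raise ValueError("oblast_levels required when beta_oblast is non-empty")
        levels = list(oblast_levels)
        idx = levels.index(str(subject["oblast"]))
        if idx > 0:
            lp += params.beta_oblast[idx - 1]
    if params.beta_age.size:
        if age_cutpoints is None:
            raise ValueError("age_cutpoints required when beta_age is non-empty")
        k = int(np.digitize(float(subject["age_at_screening"]), np.asarray(age_cutpoints)))
        if k > 0:
            lp += params.beta_age[k - 1]
    return lp


def case_probability(params: RiskParameters, subject: Mapping, dose: float, *,
                     oblast_levels: Sequence | None = None,
                     age_cutpoints: Sequence | None = None) -> float:
    """Probability of being a prevalent case under the EOR logistic model.

    ``subject`` is any mapping with keys ``gender``, ``oblast``,
    ``age_at_exposure``, ``age_at_screening`` (missing oblast/age terms are
    allowed when the corresponding coefficient vectors are empty).
    Raises ``ValueError`` if ``1 + EOR <= 0`` for this subject.
    """
    eor = excess_odds_ratio(
        params, dose,
        e=float(subject.get("age_at_exposure", EXPOSURE_AGE_CENTER)),
        a=float(subject.get("age_at_screening", SCREENING_AGE_CENTER)),
        sex=subject.get("gender", "female"),
    )
    if 1.0 + eor <= 0.0:
        raise ValueError(f"1 + EOR = {1 + eor:g} <= 0: probability undefined")
    t = _baseline_lp(params, subject, oblast_levels, age_cutpoints) + np.log1p(eor)
    return float(expit(t))


def log_likelihood(params: RiskParameters, cohort: pd.DataFrame, doses, *,
                   oblast_levels: Sequence | None = None,
                   age_cutpoints: Sequence | None = None) -> float:
    """Bernoulli log-likelihood of the cohort at the given dose vector.

    The deviance used in model-comparison reports is ``-2 *`` this value.
    A parameter point violating ``1 + EOR > 0`` for any subject yields the
    large finite penalty :data:`PENALTY_LOGLIK` (plus slope) rather than an
    exception, so that optimizers can recover.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.shape != (len(cohort),):
        raise ValueError("doses must align with the cohort")
    baseline = set()
    if "gender" in cohort:
        baseline.add("sex")
    if params.beta_oblast.size:
        baseline.add("oblast")
    if params.beta_age.size:
        baseline.add("age")
    spec = ModelSpec(
        dose_response="linear_exponential",
        modifiers=frozenset(MODIFIERS),
        baseline=frozenset(baseline),
    )
    if params.beta_age.size and age_cutpoints is None:
        raise ValueError("age_cutpoints required when beta_age is non-empty")
    design = CohortDesign(cohort, spec, oblast_levels=oblast_levels,
                          age_cutpoints=age_cutpoints if params.beta_age.size else None)
    if params.beta_oblast.size and params.beta_oblast.size != len(design.oblast_levels) - 1:
        raise ValueError("beta_oblast length does not match oblast levels")
    return design.loglik(design.pack(params), doses)
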