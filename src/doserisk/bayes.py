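"""Bayesian model averaging over dose realizations by MCMC.

The dose-realization index theta (1..M) is treated as a latent variable with
a multinomial distribution whose probability vector carries a Dirichlet(w)
hyperprior; at w = 1 the realizations are a priori equiprobable and the
Dirichlet can be marginalized out exactly (collapsed), leaving a symmetric
prior over the index.  Continuous risk parameters receive normal priors
(default Normal(0, 10^2), weakly informative).

Sampling is Metropolis-within-Gibbs: componentwise adaptive random-walk
updates of the continuous parameters against the cohort likelihood at the
current realization column times the priors, and an index update that is
either a uniform-proposal Metropolis step (one cohort-likelihood evaluation
per sweep; the default for large M) or an exact Gibbs draw over all M
columns (the default for M <= 50).  Both leave the same stationary
distribution invariant.  Proposal scales adapt during burn-in only (target
acceptance 0.2-0.4) and are frozen afterwards to preserve detailed balance.

Reported are the marginal posterior modes by 1-D kernel density estimation
on pooled chains, 95% equal-tail credible intervals, the deviance
information criterion, and the Gelman-Rubin potential scale reduction
factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .dosimetry import DoseRealizationMatrix
from .ml import fit_ml
from .risk import CohortDesign, ModelSpec

__all__ = ["PriorSpec", "PosteriorTraces", "BayesResult", "run_mcmc",
           "summarize_posterior", "compute_dic", "compute_psrf"]

_ADAPT_INTERVAL = 100


@dataclass
class PriorSpec:
    """Normal priors for the continuous parameters and the Dirichlet weight.

    ``mean``/``sd`` may be scalars (applied to every parameter) or dicts
    keyed by parameter name with a ``"default"`` fallback.
    """

    mean: float | dict = 0.0
    sd: float | dict = 10.0
    dirichlet_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.dirichlet_weight <= 0:
            raise ValueError("dirichlet_weight must be > 0")
        sds = self.sd.values() if isinstance(self.sd, dict) else [self.sd]
        if any(s <= 0 for s in sds):
            raise ValueError("prior sds must be > 0")

    def arrays(self, names) -> tuple[np.ndarray, np.ndarray]:
        def pull(v, name):
            return v.get(name, v.get("default", 0.0 if v is self.mean else 10.0)) \
                if isinstance(v, dict) else v
        mu = np.array([pull(self.mean, n) for n in names], dtype=float)
        sd = np.array([pull(self.sd, n) for n in names], dtype=float)
        return mu, sd


@dataclass
class PosteriorTraces:
    """Per-chain MCMC draws of continuous parameters and the realization
    index (1-based), with acceptance diagnostics and the seed ledger."""

    param_names: list
    draws: np.ndarray          # (chains, n_draws, n_params)
    index: np.ndarray          # (chains, n_draws), values in 1..M
    loglik: np.ndarray         # (chains, n_draws) cohort loglik at the draw
    acceptance: dict           # per-parameter post-burn-in acceptance rates
    index_acceptance: float
    n_realizations: int
    burn_in: int
    seed: int
    chain_seeds: list
    proposal_scales: np.ndarray

    def __post_init__(self) -> None:
        c, d, p = self.draws.shape
        if self.index.shape != (c, d) or self.loglik.shape != (c, d):
            raise ValueError("trace arrays must agree in chains and draws")
        if self.index.min() < 1 or self.index.max() > self.n_realizations:
            raise ValueError("index trace outside 1..M")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def pooled(self, parameter: str) -> np.ndarray:
        j = self.param_names.index(parameter)
        return self.draws[:, :, j].ravel()

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, draw, parameter columns, realization index)."""
        c, d, p = self.draws.shape
        out = {"chain": np.repeat(np.arange(c), d),
               "draw": np.tile(np.arange(d), c)}
        for j, name in enumerate(self.param_names):
            out[name] = self.draws[:, :, j].ravel()
        out["realization_index"] = self.index.ravel()
        return pd.DataFrame(out)


@dataclass
class BayesResult:
    """Maximum-posterior (marginal KDE mode) estimates, 95% equal-tail BCIs,
    DIC and per-parameter PSRF."""

    max_posterior: dict
    bci: dict
    dic: float | None
    psrf: dict
    posterior_mean: dict = field(default_factory=dict)


def run_mcmc(cohort: pd.DataFrame, matrix: DoseRealizationMatrix,
             spec: ModelSpec, priors: PriorSpec | None = None,
             chains: int = 3, burn_in: int = 10000, draws: int = 20000,
             seed: int = 0, index_update: str = "auto",
             start=None) -> PosteriorTraces:
    """Sample the joint posterior of the risk parameters and the realization
    index.  ``draws`` is the total post-burn-in sample pooled over chains
    (split evenly).  Reproducible from ``seed``; chains start overdispersed
    around the regression-calibration MLE.
    """
    if draws < 1:
        raise ValueError("draws must be >= 1")
    if index_update not in ("auto", "metropolis", "gibbs"):
        raise ValueError("index_update must be auto, metropolis or gibbs")
    priors = priors or PriorSpec()
    design = CohortDesign(cohort, spec)
    names = list(design.param_names)
    mu0, sd0 = priors.arrays(names)
    M = matrix.n_realizations
    use_gibbs = index_update == "gibbs" or (index_update == "auto" and M <= 50)
    per_chain = int(np.ceil(draws / chains))

    if start is not None:
        theta_center = design.pack(start)
    else:
        rc = fit_ml(cohort, matrix.subject_means(), spec, design=design)
        theta_center = rc.theta
    init_scale = np.maximum(0.05, 0.2 * np.maximum(np.abs(theta_center), 0.1))

    ss = np.random.SeedSequence(seed)
    chain_ss = ss.spawn(chains)
    chain_seeds = [int(s.generate_state(1)[0]) for s in chain_ss]

    def loglik(theta, col):
        # exact likelihood with -inf outside the support: infeasible
        # proposals are rejected outright
        return design.loglik_strict(theta, matrix.doses[:, col])

    all_draws = np.empty((chains, per_chain, len(names)))
    all_index = np.empty((chains, per_chain), dtype=int)
    all_ll = np.empty((chains, per_chain))
    acc_counts = np.zeros(len(names))
    idx_acc = 0
    idx_props = 0
    scales_out = None

    for c in range(chains):
        rng = np.random.default_rng(chain_ss[c])
        # overdispersed feasible start
        for _ in range(50):
            theta = theta_center + 3.0 * init_scale * rng.standard_normal(len(names))
            col = int(rng.integers(M))
            ll = loglik(theta, col)
            if np.isfinite(ll):
                break
        else:
            theta, col = theta_center.copy(), 0
            ll = loglik(theta, col)
        lprior = -0.5 * np.sum(((theta - mu0) / sd0) ** 2)
        scales = init_scale.copy()
        window_acc = np.zeros(len(names))
        window_n = 0

        for it in range(burn_in + per_chain):
            adapting = it < burn_in
            for j in range(len(names)):
                prop = theta.copy()
                prop[j] += scales[j] * rng.standard_normal()
                ll_p = loglik(prop, col)
                lp_p = -0.5 * np.sum(((prop - mu0) / sd0) ** 2)
                if np.isfinite(ll_p) and \
                        np.log(rng.random()) < (ll_p + lp_p) - (ll + lprior):
                    theta, ll, lprior = prop, ll_p, lp_p
                    window_acc[j] += 1
                    if not adapting:
                        acc_counts[j] += 1
            window_n += 1
            if adapting and window_n == _ADAPT_INTERVAL:
                rates = window_acc / _ADAPT_INTERVAL
                if np.any(rates == 0):
                    warnings.warn("all proposals rejected over a full "
                                  "adaptation window: chain may be stuck",
                                  stacklevel=2)
                scales *= np.exp(np.clip(rates - 0.3, -0.5, 0.5))
                window_acc[:] = 0
                window_n = 0

            # index update (collapsed Dirichlet, symmetric at w = 1)
            if use_gibbs:
                lvec = design.loglik_columns(theta, matrix.doses)
                w = np.exp(lvec - lvec.max())
                w /= w.sum()
                col = int(rng.choice(M, p=w))
                ll = float(lvec[col])
            else:
                prop_col = int(rng.integers(M))
                if prop_col != col:
                    ll_p = loglik(theta, prop_col)
                    if not adapting:
                        idx_props += 1
                    if np.log(rng.random()) < ll_p - ll:
                        col, ll = prop_col, ll_p
                        if not adapting:
                            idx_acc += 1

            if not adapting:
                t = it - burn_in
                all_draws[c, t] = theta
                all_index[c, t] = col + 1
                all_ll[c, t] = ll
        scales_out = scales

    n_updates = chains * per_chain
    return PosteriorTraces(
        param_names=names,
        draws=all_draws,
        index=all_index,
        loglik=all_ll,
        acceptance={n: acc_counts[j] / n_updates for j, n in enumerate(names)},
        index_acceptance=(idx_acc / idx_props) if idx_props else 1.0,
        n_realizations=M,
        burn_in=burn_in,
        seed=seed,
        chain_seeds=chain_seeds,
        proposal_scales=scales_out,
    )


def _kde_mode(x: np.ndarray) -> float:
    if np.ptp(x) < 1e-12:
        return float(x[0])
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[int(np.argmax(kde(grid)))])


def summarize_posterior(traces: PosteriorTraces, cohort: pd.DataFrame = None,
                        matrix: DoseRealizationMatrix = None,
                        spec: ModelSpec = None) -> BayesResult:
    """Marginal KDE modes, 95% equal-tail BCIs, PSRF, and (when the data are
    supplied) the DIC.  Requires at least 1,000 pooled post-burn-in draws."""
    pooled_n = traces.draws.shape[0] * traces.draws.shape[1]
    if pooled_n < 1000:
        raise ValueError(f"need >= 1000 pooled draws, got {pooled_n}")
    modes, bci, psrf, pmean = {}, {}, {}, {}
    for name in traces.param_names:
        x = traces.pooled(name)
        modes[name] = _kde_mode(x)
        lo, hi = np.quantile(x, [0.025, 0.975])
        bci[name] = (float(lo), float(hi))
        pmean[name] = float(x.mean())
        psrf[name] = compute_psrf(traces, name)
    dic = None
    if cohort is not None and matrix is not None:
        dic = compute_dic(traces, cohort, matrix, spec=spec)
    return BayesResult(max_posterior=modes, bci=bci, dic=dic, psrf=psrf,
                       posterior_mean=pmean)


def compute_dic(traces: PosteriorTraces, cohort: pd.DataFrame,
                matrix: DoseRealizationMatrix,
                spec: ModelSpec = None) -> float:
    """DIC = Dbar + pD with pD = Dbar - D(theta_bar).

    Per-draw deviance is -2x the cohort log-likelihood at that draw's
    parameters and realization column (recorded during sampling).  The
    plug-in point uses the posterior means of the continuous parameters and
    the modal realization column (a mean over an unordered index is
    undefined).
    """
    dbar = float(np.mean(-2.0 * traces.loglik))
    theta_bar = traces.draws.reshape(-1, traces.draws.shape[2]).mean(axis=0)
    idx_flat = traces.index.ravel()
    modal_col = int(np.bincount(idx_flat).argmax()) - 1
    if spec is None:
        spec = _infer_spec(traces.param_names)
    design = CohortDesign(cohort, spec)
    d_hat = -2.0 * design.loglik(theta_bar, matrix.doses[:, modal_col])
    pd_eff = dbar - d_hat
    return dbar + pd_eff


def _infer_spec(names) -> ModelSpec:
    modifiers = set()
    if "kappa" in names:
        modifiers.add("age_at_exposure")
    if "tau" in names:
        modifiers.add("age_at_screening")
    if "eta" in names:
        modifiers.add("sex")
    if "gamma" in names:
        dr = "linear_exponential"
    elif "alpha" in names:
        dr = "linear"
    else:
        dr = "null"
    baseline = set()
    if "beta_sex" in names:
        baseline.add("sex")
    if any(n.startswith("beta_oblast_") for n in names):
        baseline.add("oblast")
    if any(n.startswith("beta_age_") for n in names):
        baseline.add("age")
    return ModelSpec(dose_response=dr, modifiers=frozenset(modifiers),
                     baseline=frozenset(baseline))


def compute_psrf(traces: PosteriorTraces, parameter: str) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    sqrt(Vhat / W) with W the mean within-chain variance, B/n the variance
    of chain means, and Vhat = (n-1)/n * W + B/n.  Values near 1 indicate
    convergence.  Zero within-chain variance yields 1.0 (all chains at the
    same point) or inf (chains stuck at different points), with a warning.
    """
    j = traces.param_names.index(parameter)
    x = traces.draws[:, :, j]
    if x.shape[0] < 2:
        raise ValueError("PSRF requires at least 2 chains")
    n = x.shape[1]
    within = x.var(axis=1, ddof=1)
    W = float(within.mean())
    B_over_n = float(x.mean(axis=1).var(ddof=1))
    if W <= 0:
        warnings.warn(f"zero within-chain variance for {parameter}",
                      stacklevel=2)
        return 1.0 if B_over_n <= 0 else float("inf")
    vhat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(vhat / W))
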