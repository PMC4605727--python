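"""Bayesian model averaging over dose realizations: sampler, summaries,
DIC and Gelman-Rubin diagnostics."""

import numpy as np
import pytest
from scipy.stats import chisquare

from doserisk import (DoseRealizationMatrix, ModelSpec, PriorSpec,
                      SimulationConfig, compute_dic, compute_psrf, fit_mcml,
                      fit_ml, run_mcmc, simulate_cohort, summarize_posterior)
from doserisk.bayes import PosteriorTraces, _kde_mode


def make_traces(draws, index=None, loglik=None, names=("alpha",), M=4):
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    c, d, _ = draws.shape
    return PosteriorTraces(
        param_names=list(names), draws=draws,
        index=np.ones((c, d), dtype=int) if index is None else index,
        loglik=np.zeros((c, d)) if loglik is None else loglik,
        acceptance={}, index_acceptance=1.0, n_realizations=M,
        burn_in=0, seed=0, chain_seeds=[0] * c,
        proposal_scales=np.ones(len(names)))


@pytest.fixture(scope="module")
def small_run():
    cfg = SimulationConfig(n_subjects=800, n_realizations=5, seed=101,
                           target_cases=40)
    cohort, true_doses, matrix = simulate_cohort(cfg)
    spec = ModelSpec(dose_response="linear")
    traces = run_mcmc(cohort, matrix, spec, chains=3, burn_in=600, draws=2400,
                      seed=11)
    return cohort, matrix, spec, traces


class TestSampler:
    def test_same_seed_same_traces(self):
        cfg = SimulationConfig(n_subjects=300, n_realizations=4, seed=71,
                               target_cases=15)
        cohort, _, matrix = simulate_cohort(cfg)
        spec = ModelSpec(dose_response="linear")
        kw = dict(chains=2, burn_in=100, draws=600, seed=9)
        t1 = run_mcmc(cohort, matrix, spec, **kw)
        t2 = run_mcmc(cohort, matrix, spec, **kw)
        assert np.array_equal(t1.draws, t2.draws)
        assert np.array_equal(t1.index, t2.index)

    def test_single_realization_reduces_to_bayesian_logistic(self):
        """M = 1: the index is constant and the posterior mean of alpha sits
        near the MLE for weak priors and moderate N."""
        cfg = SimulationConfig(n_subjects=2000, n_realizations=1, seed=73,
                               target_cases=120)
        cohort, _, matrix = simulate_cohort(cfg)
        spec = ModelSpec(dose_response="linear")
        traces = run_mcmc(cohort, matrix, spec, chains=3, burn_in=800,
                          draws=3600, seed=13)
        assert np.all(traces.index == 1)
        mle = fit_ml(cohort, matrix.doses[:, 0], spec).estimate("alpha")
        alpha = traces.pooled("alpha")
        assert abs(alpha.mean() - mle) < 0.6 * alpha.std()

    def test_flat_likelihood_visits_columns_uniformly(self):
        """A dose-free model makes all realizations equivalent: the index
        trace must be uniform over the M = 10 columns."""
        cfg = SimulationConfig(n_subjects=400, n_realizations=10, seed=79,
                               target_cases=20)
        cohort, _, matrix = simulate_cohort(cfg)
        spec = ModelSpec(dose_response="null")
        traces = run_mcmc(cohort, matrix, spec, chains=2, burn_in=200,
                          draws=4000, seed=17, index_update="metropolis")
        counts = np.bincount(traces.index.ravel(), minlength=11)[1:]
        assert chisquare(counts).pvalue > 0.01

    def test_index_trace_within_bounds(self, small_run):
        _, matrix, _, traces = small_run
        assert traces.index.min() >= 1
        assert traces.index.max() <= matrix.n_realizations

    def test_invalid_arguments_rejected(self, small_run):
        cohort, matrix, spec, _ = small_run
        with pytest.raises(ValueError):
            run_mcmc(cohort, matrix, spec, draws=0)
        with pytest.raises(ValueError):
            run_mcmc(cohort, matrix, spec, index_update="slice")
        with pytest.raises(ValueError):
            PriorSpec(sd=-1.0)


class TestSummaries:
    def test_normal_trace_mode_and_bci(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 1.0, 50000).reshape(2, 25000)
        res = summarize_posterior(make_traces(x))
        # the KDE mode of a 50k-draw normal sample has Monte Carlo sd ~0.07
        assert res.max_posterior["alpha"] == pytest.approx(2.0, abs=0.15)
        lo, hi = res.bci["alpha"]
        assert lo == pytest.approx(2 - 1.959964, abs=0.08)
        assert hi == pytest.approx(2 + 1.959964, abs=0.08)

    def test_point_mass_trace(self):
        x = np.full((2, 1000), 3.25)
        res = summarize_posterior(make_traces(x))
        assert res.max_posterior["alpha"] == 3.25
        assert res.bci["alpha"] == (3.25, 3.25)

    def test_skewed_trace_mode_below_median_below_mean(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0.0, 0.8, 60000).reshape(2, 30000)
        res = summarize_posterior(make_traces(x))
        mode = res.max_posterior["alpha"]
        assert mode < np.median(x) < x.mean()

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            summarize_posterior(make_traces(np.zeros((2, 100))))

    def test_kde_mode_degenerate_input(self):
        assert _kde_mode(np.full(50, 1.5)) == 1.5


class TestDIC:
    def test_degenerate_posterior_has_zero_complexity(self, toy_cohort,
                                                      toy_doses):
        mat = DoseRealizationMatrix(toy_doses[:, None], toy_doses,
                                    toy_cohort["subject_id"].to_numpy(),
                                    np.zeros(1, dtype=int))
        spec = ModelSpec(dose_response="linear", baseline=frozenset())
        from doserisk.risk import CohortDesign
        design = CohortDesign(toy_cohort, spec)
        theta0 = np.array([-1.0, 0.5])
        ll = design.loglik(theta0, toy_doses)
        traces = make_traces(np.tile(theta0, (2, 600, 1)),
                             loglik=np.full((2, 600), ll),
                             names=design.param_names, M=1)
        dic = compute_dic(traces, toy_cohort, mat, spec=spec)
        assert dic == pytest.approx(-2 * ll, abs=1e-9)  # pD = 0

    def test_effective_parameters_near_count_at_scale(self, small_run):
        """For a near-normal posterior, pD approaches the number of free
        continuous parameters."""
        cohort, matrix, spec, traces = small_run
        dic = compute_dic(traces, cohort, matrix, spec=spec)
        dbar = float(np.mean(-2 * traces.loglik))
        pd_eff = dic - dbar
        p = len(traces.param_names)
        assert 0.4 * p < pd_eff < 1.8 * p

    def test_dose_ignoring_parameter_leaves_deviance_mean(self, small_run):
        """With all doses zero the dose slope is ignored by the likelihood:
        mean deviance matches the dose-free model within Monte Carlo error."""
        cohort, matrix, spec, _ = small_run
        zero = DoseRealizationMatrix(np.zeros_like(matrix.doses),
                                     np.zeros(matrix.n_subjects),
                                     matrix.subject_ids,
                                     matrix.realization_seeds)
        t_lin = run_mcmc(cohort, zero, spec, chains=2, burn_in=300, draws=1600,
                         seed=23)
        t_null = run_mcmc(cohort, zero, ModelSpec(dose_response="null"),
                          chains=2, burn_in=300, draws=1600, seed=23)
        d_lin = np.mean(-2 * t_lin.loglik)
        d_null = np.mean(-2 * t_null.loglik)
        assert d_lin == pytest.approx(d_null, abs=3.0)


class TestPSRF:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (3, 10000))
        assert compute_psrf(make_traces(x), "alpha") < 1.05

    def test_shifted_chains_far_above_one(self):
        rng = np.random.default_rng(3)
        x = np.stack([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
        assert compute_psrf(make_traces(x), "alpha") > 1.5

    def test_duplicated_chain_split_is_one(self):
        rng = np.random.default_rng(4)
        half = rng.normal(0, 1, 4000)
        x = np.stack([half, half])
        assert compute_psrf(make_traces(x), "alpha") == pytest.approx(1.0,
                                                                      abs=0.02)

    def test_zero_within_variance_sentinels(self):
        with pytest.warns(UserWarning, match="zero within-chain"):
            assert compute_psrf(make_traces(np.full((2, 100), 1.0)),
                                "alpha") == 1.0
        bad = np.stack([np.full(100, 0.0), np.full(100, 5.0)])
        with pytest.warns(UserWarning, match="zero within-chain"):
            assert np.isinf(compute_psrf(make_traces(bad), "alpha"))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            compute_psrf(make_traces(np.zeros((1, 100))), "alpha")


class TestPriorSensitivity:
    def test_widening_priors_moves_mode_toward_mcml(self):
        cfg = SimulationConfig(n_subjects=1200, n_realizations=10, seed=83,
                               target_cases=70)
        cohort, _, matrix = simulate_cohort(cfg)
        spec = ModelSpec(dose_response="linear")
        target = fit_mcml(cohort, matrix, spec).estimate("alpha")
        modes = []
        for sd in (0.25, 2.5):
            priors = PriorSpec(sd={"alpha": sd, "default": 10.0})
            traces = run_mcmc(cohort, matrix, spec, priors=priors, chains=2,
                              burn_in=500, draws=2000, seed=29)
            modes.append(summarize_posterior(traces).max_posterior["alpha"])
        assert abs(modes[1] - target) < abs(modes[0] - target)
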