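"""Dose equations and the shared/unshared Monte Carlo realization machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from doserisk import (DoseRealizationMatrix, DosimetryConstants,
                      ErrorParameterSpec, ThyroidActivityProfile,
                      default_error_specs, dump_error_specs, ecological_dose,
                      generate_realizations, instrumental_dose,
                      load_error_specs, read_matrix_csv, realization_summary,
                      write_matrix_csv)

CONST = DosimetryConstants()


def profile_with(activity_fn, mass=10.0, measured=50.0, t_m=30.0):
    t = np.arange(0.0, 67.0)
    return ThyroidActivityProfile("s1", t, activity_fn(t), measured, t_m, mass)


class TestEcologicalDose:
    def test_zero_activity_zero_dose(self):
        prof = profile_with(lambda t: np.zeros_like(t))
        assert ecological_dose(prof, CONST) == 0.0

    def test_constant_activity_closed_form(self):
        # integral of constant Q over [0, T] is Q*T, so dose = Uc*Eth*Q*T/m
        q, m = 40.0, 8.0
        prof = profile_with(lambda t: np.full_like(t, q), mass=m)
        expected = 13.82 * CONST.energy_per_decay * q * 66.0 / m
        assert ecological_dose(prof, CONST) == pytest.approx(expected, rel=1e-12)

    def test_doubling_mass_halves_dose(self):
        prof1 = profile_with(lambda t: 30 * np.exp(-t / 8), mass=5.0)
        prof2 = profile_with(lambda t: 30 * np.exp(-t / 8), mass=10.0)
        assert ecological_dose(prof1, CONST) == pytest.approx(
            2 * ecological_dose(prof2, CONST), rel=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(0.1, 50.0), st.floats(0.2, 40.0))
    def test_linear_in_activity_inverse_in_mass(self, scale, mass):
        base = profile_with(lambda t: 20 * np.exp(-t / 10), mass=1.0)
        scaled = profile_with(lambda t: scale * 20 * np.exp(-t / 10), mass=mass)
        assert ecological_dose(scaled, CONST) == pytest.approx(
            scale / mass * ecological_dose(base, CONST), rel=1e-9)

    def test_profile_must_cover_window(self):
        t = np.arange(0.0, 30.0)
        prof = ThyroidActivityProfile("s", t, np.ones_like(t), 1.0, 10.0, 5.0)
        with pytest.raises(ValueError, match="cover"):
            ecological_dose(prof, CONST)

    def test_positive_mass_enforced(self):
        with pytest.raises(ValueError, match="thyroid_mass"):
            profile_with(lambda t: np.ones_like(t), mass=0.0)


class TestInstrumentalDose:
    def test_identity_when_measured_equals_modelled(self):
        prof = profile_with(lambda t: 30 * np.exp(-t / 8))
        prof.measured_activity = prof.activity_at(prof.measurement_time)
        d_ecol = ecological_dose(prof, CONST)
        assert instrumental_dose(prof, d_ecol) == pytest.approx(d_ecol, rel=1e-12)

    def test_linear_scaling_in_measured_activity(self):
        prof = profile_with(lambda t: 30 * np.exp(-t / 8))
        prof.measured_activity = 2 * prof.activity_at(prof.measurement_time)
        d_ecol = ecological_dose(prof, CONST)
        assert instrumental_dose(prof, d_ecol) == pytest.approx(2 * d_ecol,
                                                                rel=1e-12)

    def test_zero_measured_activity_zero_dose(self):
        prof = profile_with(lambda t: 30 * np.exp(-t / 8), measured=0.0)
        assert instrumental_dose(prof, ecological_dose(prof, CONST)) == 0.0

    def test_zero_modelled_activity_is_undefined_scaling(self):
        prof = profile_with(lambda t: np.where(t < 20, 10.0, 0.0), t_m=40.0)
        with pytest.raises(ZeroDivisionError):
            instrumental_dose(prof, 1.0)


class TestGenerateRealizations:
    def test_degenerate_specs_reproduce_true_doses(self, zero_error_specs):
        true = np.array([0.2, 1.0, 3.5])
        mat = generate_realizations(true, zero_error_specs, M=5, seed=0)
        assert np.array_equal(mat.doses, np.tile(true[:, None], (1, 5)))
        assert np.array_equal(mat.deterministic, true)

    def test_unshared_sample_gsd_matches_spec(self):
        g = 1.8
        spec = [ErrorParameterSpec("u", "unshared", "lognormal", {"gsd": g})]
        mat = generate_realizations(np.ones(5), spec, M=10000, seed=3)
        gsd = np.exp(np.std(np.log(mat.doses), axis=1, ddof=1))
        assert np.allclose(gsd, g, rtol=0.02)

    def test_shared_draw_constant_within_column(self):
        spec = [ErrorParameterSpec("s", "shared", "lognormal", {"gsd": 2.0})]
        true = np.array([0.5, 1.0, 2.0, 4.0])
        mat = generate_realizations(true, spec, M=50, seed=1)
        ratios = mat.doses / true[:, None]
        assert np.allclose(ratios, ratios[0, :][None, :], rtol=1e-12)

    def test_sharing_groups_induce_within_group_correlation(self):
        spec = [ErrorParameterSpec("s", "shared", "lognormal", {"gsd": 2.0},
                                   sharing_group="settlement")]
        labels = np.array(["a", "a", "b", "b"])
        mat = generate_realizations(np.ones(4), spec, M=30, seed=2,
                                    group_labels={"settlement": labels})
        assert np.allclose(mat.doses[0], mat.doses[1])
        assert np.allclose(mat.doses[2], mat.doses[3])
        assert not np.allclose(mat.doses[0], mat.doses[2])

    def test_unshared_ratios_independent_across_subjects(self):
        spec = [ErrorParameterSpec("u", "unshared", "lognormal", {"gsd": 2.0})]
        mat = generate_realizations(np.ones(1000), spec, M=2, seed=4)
        rho = spearmanr(mat.doses[:, 0], mat.doses[:, 1]).statistic
        assert abs(rho) < 0.08

    def test_unit_median_errors_preserve_median_dose(self):
        specs = [ErrorParameterSpec("s", "shared", "lognormal", {"gsd": 1.3}),
                 ErrorParameterSpec("u", "unshared", "lognormal", {"gsd": 1.8})]
        true = np.array([0.5, 1.0, 2.0])
        mat = generate_realizations(true, specs, M=10000, seed=5)
        med = np.median(mat.doses, axis=1)
        assert np.allclose(med, true, rtol=0.03)

    def test_reproducible_from_seed(self):
        spec = [ErrorParameterSpec("u", "unshared", "lognormal", {"gsd": 1.5})]
        m1 = generate_realizations(np.ones(10), spec, M=7, seed=11)
        m2 = generate_realizations(np.ones(10), spec, M=7, seed=11)
        assert np.array_equal(m1.doses, m2.doses)
        assert np.array_equal(m1.realization_seeds, m2.realization_seeds)

    def test_missing_group_labels_is_config_error(self):
        spec = [ErrorParameterSpec("s", "shared", "lognormal", {"gsd": 2.0},
                                   sharing_group="village")]
        with pytest.raises(ValueError, match="village"):
            generate_realizations(np.ones(3), spec, M=2, seed=0)

    def test_unknown_distribution_is_config_error(self):
        with pytest.raises(ValueError, match="distribution"):
            ErrorParameterSpec("x", "unshared", "weibull", {"k": 2})

    def test_gsd_below_one_rejected(self):
        with pytest.raises(ValueError, match="gsd"):
            ErrorParameterSpec("x", "unshared", "lognormal", {"gsd": 0.9})


class TestRealizationSummary:
    def test_constant_row_mean_and_unit_gsd(self):
        mat = DoseRealizationMatrix(np.full((1, 6), 2.5), np.array([2.5]),
                                    np.array([1]), np.zeros(6, dtype=int))
        s = realization_summary(mat)
        assert s.per_subject["mean"].iloc[0] == pytest.approx(2.5)
        assert s.per_subject["gsd"].iloc[0] == pytest.approx(1.0)

    def test_lognormal_row_gsd_converges_to_exp_sigma(self):
        sigma = 0.6
        rng = np.random.default_rng(0)
        row = np.exp(rng.normal(0.0, sigma, 10000))
        mat = DoseRealizationMatrix(row[None, :], np.array([1.0]),
                                    np.array([1]), np.zeros(10000, dtype=int))
        s = realization_summary(mat)
        assert s.per_subject["gsd"].iloc[0] == pytest.approx(np.exp(sigma),
                                                             rel=0.02)

    def test_two_subject_toy_means(self):
        mat = DoseRealizationMatrix(np.array([[1.0, 2.0], [3.0, 3.0]]),
                                    np.array([1.5, 3.0]), np.array([1, 2]),
                                    np.zeros(2, dtype=int))
        s = realization_summary(mat)
        assert np.allclose(s.per_subject["mean"], [1.5, 3.0])
        assert s.cohort_mean == pytest.approx(2.25)

    def test_zero_dose_subject_flagged_and_excluded(self):
        mat = DoseRealizationMatrix(np.array([[0.0, 2.0], [3.0, 3.0]]),
                                    np.array([1.0, 3.0]), np.array([1, 2]),
                                    np.zeros(2, dtype=int))
        with pytest.warns(UserWarning, match="zero doses"):
            s = realization_summary(mat)
        assert bool(s.per_subject["has_zero"].iloc[0])
        assert np.isnan(s.per_subject["gsd"].iloc[0])
        assert s.mean_gsd == pytest.approx(1.0)

    def test_column_permutation_leaves_summaries_unchanged(self):
        rng = np.random.default_rng(1)
        doses = rng.lognormal(0, 0.5, (5, 40))
        mat = DoseRealizationMatrix(doses, doses.mean(axis=1), np.arange(5),
                                    np.zeros(40, dtype=int))
        perm = rng.permutation(40)
        mat_p = DoseRealizationMatrix(doses[:, perm], mat.deterministic,
                                      mat.subject_ids, mat.realization_seeds)
        s, sp = realization_summary(mat), realization_summary(mat_p)
        assert np.allclose(s.per_subject["mean"], sp.per_subject["mean"])
        assert np.allclose(s.per_subject["gsd"], sp.per_subject["gsd"])

    def test_single_realization_rejected(self):
        mat = DoseRealizationMatrix(np.ones((2, 1)), np.ones(2),
                                    np.array([1, 2]), np.zeros(1, dtype=int))
        with pytest.raises(ValueError):
            realization_summary(mat)


class TestPosteriorDoseRealizations:
    def test_realization_mean_converges_to_central_estimate(self):
        """The per-subject mean over many posterior draws approximates the
        system's central (posterior-mean) dose estimate."""
        from doserisk import posterior_dose_realizations
        rng = np.random.default_rng(0)
        true = rng.lognormal(np.log(0.68) - 0.5 * 1.6**2, 1.6, 50)
        mat = posterior_dose_realizations(true, error_gsd=1.76, dose_mean=0.68,
                                          dose_sigma_log=1.6, M=4000, seed=1)
        assert np.allclose(mat.subject_means(), mat.deterministic, rtol=0.05)

    def test_zero_error_returns_true_doses(self):
        from doserisk import posterior_dose_realizations
        true = np.array([0.1, 0.7, 2.5])
        mat = posterior_dose_realizations(true, error_gsd=1.0, dose_mean=0.68,
                                          dose_sigma_log=1.6, M=3, seed=2)
        assert np.allclose(mat.doses, true[:, None])
        assert np.allclose(mat.deterministic, true)

    def test_shrinkage_toward_prior_mean(self):
        """Posterior-mean doses are pulled toward the cohort prior: less
        log-scale spread than the latent true doses."""
        from doserisk import posterior_dose_realizations
        rng = np.random.default_rng(3)
        true = rng.lognormal(np.log(0.68) - 0.5 * 1.6**2, 1.6, 2000)
        mat = posterior_dose_realizations(true, error_gsd=2.5, dose_mean=0.68,
                                          dose_sigma_log=1.6, M=2, seed=4)
        assert np.std(np.log(mat.deterministic)) < np.std(np.log(true))


class TestDefaultErrorFixture:
    def test_per_subject_gsd_structure(self):
        n = 20000
        specs = default_error_specs(n, seed=0)
        mat = generate_realizations(np.ones(n), specs, M=60, seed=1)
        s = realization_summary(mat)
        gsd = s.per_subject["gsd"].to_numpy()
        assert 1.65 < s.mean_gsd < 1.87        # arithmetic mean near 1.76
        assert 1.62 < s.geometric_mean_gsd < 1.83
        # the spread spans roughly 1.3 to 5 (quantiles, robust to the
        # sampling noise of a finite-M GSD estimate)
        assert 1.25 < np.quantile(gsd, 0.001) < 1.5
        assert 3.0 < np.quantile(gsd, 0.999) < 6.0
        # dominant spread comes from the unshared heterogeneous component
        assert np.quantile(gsd, 0.99) > 2.8


class TestIO:
    def test_matrix_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        mat = generate_realizations(
            rng.lognormal(0, 1, 8),
            [ErrorParameterSpec("u", "unshared", "lognormal", {"gsd": 1.5})],
            M=4, seed=9)
        path = tmp_path / "matrix.csv"
        write_matrix_csv(mat, path)
        back = read_matrix_csv(path)
        assert np.allclose(back.doses, mat.doses)
        assert np.allclose(back.deterministic, mat.deterministic)
        assert np.array_equal(back.realization_seeds.astype(np.uint64),
                              mat.realization_seeds.astype(np.uint64))

    def test_error_spec_yaml_round_trip(self, tmp_path):
        specs = [
            ErrorParameterSpec("dep", "shared", "lognormal", {"gsd": 1.2},
                               sharing_group="settlement"),
            ErrorParameterSpec("meas", "unshared", "lognormal",
                               {"gsd": np.array([1.5, 2.0, 2.5])}),
            ErrorParameterSpec("cal", "fixed", params={"value": 1.05}),
        ]
        path = tmp_path / "specs.yaml"
        dump_error_specs(specs, path)
        back = load_error_specs(path)
        assert [s.name for s in back] == ["dep", "meas", "cal"]
        assert back[0].sharing_group == "settlement"
        assert np.allclose(back[1].params["gsd"], [1.5, 2.0, 2.5])
        assert back[2].params["value"] == 1.05
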