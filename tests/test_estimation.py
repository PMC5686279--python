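"""Likelihood kernel, PK/PD estimators, AIC bookkeeping, covariate LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resistpkpd.data import ObservationTable
from resistpkpd.errors import InputError, InvalidParameterError
from resistpkpd.estimation import (CovariateSpec, ErrorModel, FitResult,
                                   PKCurveFit, TumorGrowthFit, compare_models,
                                   covariate_test, fit_base_and_resistance,
                                   neg_log_likelihood)
from resistpkpd.synthetic import (canonical_population, default_design,
                                  generate_study, true_pk_parameters)


class TestErrorModel:
    def test_combined_sd(self):
        err = ErrorModel("combined", a=2.0, b=0.1)
        assert err.sd(50.0) == pytest.approx(7.0)

    def test_proportional_requires_zero_additive(self):
        with pytest.raises(InvalidParameterError):
            ErrorModel("proportional", a=1.0, b=0.1)

    def test_negative_components_rejected(self):
        with pytest.raises(InvalidParameterError):
            ErrorModel("combined", a=-1.0, b=0.1)


class TestNegLogLikelihood:
    def test_zero_residuals_reduce_to_normalization(self):
        f = np.array([10.0, 50.0, 200.0])
        err = ErrorModel("proportional", 0.0, 0.1)
        nll = neg_log_likelihood(f.copy(), f, err)
        expected = np.sum(np.log(0.1 * f * np.sqrt(2 * np.pi)))
        assert nll == pytest.approx(expected, abs=1e-12)

    def test_likelihood_maximal_at_prediction(self):
        err = ErrorModel("combined", 1.0, 0.1)
        f = np.array([50.0])
        base = neg_log_likelihood(np.array([50.0]), f, err)
        for y in (45.0, 55.0, 60.0):
            assert neg_log_likelihood(np.array([y]), f, err) > base

    def test_matches_density_sum_oracle(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(5, 500, 40)
        y = f * (1 + 0.2 * rng.normal(size=40))
        err = ErrorModel("combined", 0.5, 0.15)
        oracle = -sum(stats.norm(loc=fi, scale=0.5 + 0.15 * fi).logpdf(yi)
                      for fi, yi in zip(f, y))
        assert neg_log_likelihood(y, f, err) == pytest.approx(oracle, abs=1e-10)

    def test_censored_contribution(self):
        err = ErrorModel("combined", 1.0, 0.1)
        y = np.array([50.0, 2.0])
        f = np.array([50.0, 8.0])
        blq = np.array([False, True])
        dropped = neg_log_likelihood(y, f, err, blq=blq, blq_mode="drop")
        censored = neg_log_likelihood(y, f, err, blq=blq, loq=5.0,
                                      blq_mode="censored")
        extra = -stats.norm(loc=8.0, scale=1.8).logcdf(5.0)
        assert censored == pytest.approx(dropped + extra, abs=1e-10)


class TestPKCurveFit:
    def test_noiseless_recovery(self):
        """Exact recovery of (ke, V) from noiseless profiles."""
        pop = canonical_population(omega_scale=0.0)
        table, _ = generate_study(default_design(2), pop, model="base",
                                  seed=0, noise=False)
        fit = PKCurveFit(compound="erlotinib", mode="pooled", seed=0).fit(table)
        assert fit.params_["ke"] == pytest.approx(7.56, rel=1e-3)
        assert fit.params_["V"] == pytest.approx(0.127, rel=1e-3)
        assert "I" not in fit.params_  # fixed to 0 for erlotinib

    def test_gefitinib_estimates_I(self):
        pop = canonical_population(omega_scale=0.0)
        table, _ = generate_study(default_design(2), pop, model="base",
                                  seed=0, noise=False)
        fit = PKCurveFit(compound="gefitinib", mode="pooled", seed=0).fit(table)
        assert fit.params_["I"] == pytest.approx(0.00772, rel=1e-2)
        assert fit.params_["ke"] == pytest.approx(3.87, rel=1e-3)

    def test_single_subject_modes_agree(self):
        pop = canonical_population(omega_scale=0.0)
        design = default_design(1)
        table, _ = generate_study(design, pop, model="base", seed=4)
        sub = ObservationTable(table.df[table.df["ID"] == "S002"])
        pooled = PKCurveFit(compound="erlotinib", mode="pooled", seed=0).fit(sub)
        per = PKCurveFit(compound="erlotinib", mode="per_subject", seed=0).fit(sub)
        assert pooled.params_["ke"] == pytest.approx(per.params_["ke"], rel=1e-4)
        assert pooled.params_["V"] == pytest.approx(per.params_["V"], rel=1e-4)

    def test_no_pk_rows_errors(self):
        pop = canonical_population(omega_scale=0.0)
        table, _ = generate_study(default_design(1), pop, model="base", seed=0)
        with pytest.raises(InputError):
            PKCurveFit(compound="imatinib").fit(table)


class TestFitResultBookkeeping:
    def test_aic_identity(self):
        res = FitResult(params={"a": 1.0}, loglik=-123.456, k=5, n_obs=100,
                        error_model=ErrorModel(), converged=True)
        assert res.aic == 2 * 5 - 2 * (-123.456)

    def test_parameter_count_base_vs_resistance(self, small_study,
                                                small_study_pk):
        """No-covariate configurations expose 5 vs 7 structural parameters."""
        _, _, table, _ = small_study
        fb = TumorGrowthFit(model="base", n_starts=1, polish=0, maxfun=10,
                            seed=0).fit(table, pk_params=small_study_pk)
        fr = TumorGrowthFit(model="resistance", n_starts=1, polish=0,
                            maxfun=10, seed=0).fit(table,
                                                   pk_params=small_study_pk)
        assert fb.k_ == 5
        assert fr.k_ == 7
        assert fr.k_ - fb.k_ == 2  # beta and kSR

    def test_covariate_split_adds_one_parameter(self, small_study,
                                                small_study_pk):
        _, _, table, _ = small_study
        fit = TumorGrowthFit(model="resistance",
                             covariates=(CovariateSpec("kSR"),),
                             n_starts=1, polish=0, maxfun=10,
                             seed=0).fit(table, pk_params=small_study_pk)
        assert fit.k_ == 8
        assert "kSR__high" in fit.params_


class TestTumorGrowthFit:
    def test_recovery_no_iiv(self, small_study, small_study_pk):
        """Base-model fixed effects recovered from a noisy omega=0 study."""
        _, pop, table, _ = small_study
        fit = TumorGrowthFit(model="base", seed=0, n_starts=2,
                             tv0=100.0).fit(table, pk_params=small_study_pk)
        assert fit.params_["lambda0"] == pytest.approx(0.217, rel=0.25)
        assert fit.params_["lambda1"] == pytest.approx(42.8, rel=0.25)
        assert fit.params_["k1"] == pytest.approx(1.52, rel=0.35)
        assert fit.converged_

    def test_estimates_respect_bounds(self, small_study, small_study_pk):
        _, _, table, _ = small_study
        bounds = {"kSR": (1e-4, 0.05), "beta": (0.3, 2.0)}
        fit = TumorGrowthFit(model="resistance", bounds=bounds, n_starts=1,
                             maxfun=60, polish=0,
                             seed=0).fit(table, pk_params=small_study_pk)
        assert 1e-4 <= fit.params_["kSR"] <= 0.05
        assert 0.3 <= fit.params_["beta"] <= 2.0

    def test_missing_pk_params_errors(self, small_study):
        _, _, table, _ = small_study
        with pytest.raises(InputError):
            TumorGrowthFit(model="base").fit(table, pk_params={})

    def test_covariate_without_high_dose_subjects_errors(self, small_study,
                                                         small_study_pk):
        _, _, table, _ = small_study
        low_only = ObservationTable(
            table.df[table.df["GROUP"].isin(["vehicle", "low"])])
        with pytest.raises(InputError):
            TumorGrowthFit(model="resistance",
                           covariates=(CovariateSpec("kSR"),),
                           n_starts=1).fit(low_only, pk_params=small_study_pk)


class TestModelComparison:
    def test_identical_fits_tie(self, small_study, small_study_pk):
        _, _, table, _ = small_study
        fit = TumorGrowthFit(model="base", n_starts=1, maxfun=40, polish=0,
                             seed=0).fit(table, pk_params=small_study_pk)
        cmp = compare_models(fit, fit)
        assert cmp.tie and cmp.delta_aic == 0.0

    def test_nested_equal_loglik_penalized_by_two_per_parameter(self):
        shared = dict(loglik=-100.0, n_obs=50, error_model=ErrorModel(),
                      converged=True, data_fingerprint="x")
        small = FitResult(params={}, k=5, **shared)
        large = FitResult(params={}, k=7, **shared)
        cmp = compare_models(small, large)
        assert cmp.delta_aic == pytest.approx(2 * 2)
        assert cmp.preferred == "base"

    def test_mismatched_datasets_rejected(self):
        a = FitResult(params={}, loglik=-1, k=5, n_obs=50,
                      error_model=ErrorModel(), converged=True,
                      data_fingerprint="x")
        b = FitResult(params={}, loglik=-1, k=7, n_obs=50,
                      error_model=ErrorModel(), converged=True,
                      data_fingerprint="y")
        with pytest.raises(InputError):
            compare_models(a, b)

    def test_nesting_resistance_at_least_base(self, small_study,
                                              small_study_pk):
        """The resistance ML can never be below the base ML (kSR=0 nests)."""
        _, _, table, _ = small_study
        fb, fr, _ = fit_base_and_resistance(table, pk_params=small_study_pk,
                                            seed=0, n_starts=1, tv0=100.0)
        assert fr.loglik_ >= fb.loglik_ - 1e-6


@pytest.fixture(scope="module")
def covariate_study():
    # strong fourfold kSR difference between categories, modest noise
    pop = canonical_population(omega_scale=0.0).scaled(
        k2_high=None, ksr=8e-3, ksr_high=2e-3)
    design = default_design(4)
    table, bundle = generate_study(design, pop, model="resistance", seed=21)
    return table, true_pk_parameters(bundle)


class TestCovariateTest:
    def test_split_loglik_at_least_pooled(self, covariate_study):
        table, pk = covariate_study
        rep = covariate_test(table, "resistance", CovariateSpec("kSR"),
                             pk_params=pk, seed=0, n_starts=1, tv0=100.0,
                             polish=200)
        assert rep.loglik_split >= rep.loglik_pooled
        assert rep.df == 1
        assert 0.0 <= rep.p_value <= 1.0

    def test_fourfold_difference_detected(self, covariate_study):
        table, pk = covariate_study
        rep = covariate_test(table, "resistance", CovariateSpec("kSR"),
                             pk_params=pk, seed=0, n_starts=1, tv0=100.0,
                             polish=200)
        assert rep.p_value < 0.05
        est = rep.fit_split.params_
        assert est["kSR"] > est["kSR__high"]
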