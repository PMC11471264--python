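"""Predictive-value estimation: crude proportions and multinomial adjustment."""

import numpy as np
import pandas as pd
import pytest

from income_qba import (
    CrossTab,
    PredictiveValueMatrix,
    adjusted_predictive_values,
    crude_predictive_values,
    default_config,
    fit_multinomial,
    generate_cohort,
    implied_predictive_values,
    read_pv_csv,
    write_pv_csv,
)
from income_qba.bias_parameters import (
    BiasParameterError,
    CovariateProfile,
    stratum_covariate_means,
)
from income_qba.cohort import CohortValidationError


class TestCrudePredictiveValues:
    def test_survived_q1_row(self, validation_tab):
        pv = crude_predictive_values(validation_tab, 0)
        # row (710, 590, 405, 325, 205), total 2235
        assert pv.p[0, 0] == pytest.approx(710 / 2235)
        assert pv.p[0, 0] == pytest.approx(0.3177, abs=5e-5)

    def test_died_q4_row(self, validation_tab):
        pv = crude_predictive_values(validation_tab, 1)
        assert pv.p[3, 3] == pytest.approx(345 / 1660)
        assert pv.p[3, 3] == pytest.approx(0.2078, abs=5e-5)

    def test_diagonal_only_table(self):
        counts = np.zeros((2, 5, 5), int)
        counts[0] = np.eye(5, dtype=int) * 10
        counts[1] = np.eye(5, dtype=int) * 7
        for y in (0, 1):
            pv = crude_predictive_values(CrossTab(counts), y)
            np.testing.assert_allclose(pv.p, np.eye(5))

    def test_zero_row_total_names_row(self):
        counts = np.ones((2, 5, 5), int)
        counts[0, 2, :] = 0
        with pytest.raises(BiasParameterError, match=r"\[3\]"):
            crude_predictive_values(CrossTab(counts), 0)

    def test_wilson_bounds_bracket_estimate(self, validation_tab):
        for y in (0, 1):
            pv = crude_predictive_values(validation_tab, y)
            assert (pv.lo <= pv.p).all() and (pv.p <= pv.hi).all()
            assert (pv.lo >= 0).all() and (pv.hi <= 1).all()

    def test_crude_close_to_published_adjusted(self, validation_tab,
                                               published_pvms):
        """Crude and covariate-adjusted bias parameters are similar: every
        diagonal (PPV) cell agrees within 0.6 percentage points."""
        for y in (0, 1):
            crude = crude_predictive_values(validation_tab, y)
            dev = np.abs(np.diag(crude.p) - np.diag(published_pvms[y].p))
            assert dev.max() < 0.006


class TestMultinomialFit:
    def test_saturated_model_equals_crude(self, validation_tab,
                                          fixture_records):
        """Observed-quintile-only multinomial reproduces the crude matrix —
        the module's primary correctness anchor."""
        for y in (0, 1):
            fit = fit_multinomial(fixture_records, y, with_covariates=False)
            pred = adjusted_predictive_values(fit)
            crude = crude_predictive_values(validation_tab, y)
            assert np.abs(pred.p - crude.p).max() < 1e-6

    def test_identity_mechanism_near_perfect_prediction(self):
        """Perfect classification separates the likelihood; the unpenalized
        fit refuses with a hint, and the ridge fit predicts ~identity."""
        from dataclasses import replace
        from income_qba import MisclassMechanism
        cfg = replace(default_config(n=20_000, seed=3),
                      mechanism=MisclassMechanism(np.eye(5)))
        coh = generate_cohort(cfg)
        with pytest.raises(BiasParameterError, match="penalty"):
            fit_multinomial(coh, 0, with_covariates=True)
        fit = fit_multinomial(coh, 0, with_covariates=True, penalty=1e-3)
        prof = stratum_covariate_means(coh, 0)
        pred = adjusted_predictive_values(fit, prof)
        assert np.diag(pred.p).min() >= 0.99

    def test_parameter_recovery_against_analytic_oracle(self):
        cfg = default_config(n=100_000, seed=5)
        coh = generate_cohort(cfg)
        ipv = implied_predictive_values(cfg)
        for y in (0, 1):
            fit = fit_multinomial(coh, y, with_covariates=True)
            pred = adjusted_predictive_values(fit,
                                              stratum_covariate_means(coh, y))
            assert np.abs(pred.p - ipv[y].p).max() < 0.015

    def test_rejects_records_without_covariates(self, fixture_records):
        with pytest.raises(CohortValidationError, match="covariate"):
            fit_multinomial(fixture_records, 0, with_covariates=True)

    def test_ridge_fit_close_to_unpenalized(self, fixture_records):
        fit = fit_multinomial(fixture_records, 1, with_covariates=False)
        ridge = fit_multinomial(fixture_records, 1, with_covariates=False,
                                penalty=1e-4)
        a = adjusted_predictive_values(fit).p
        b = adjusted_predictive_values(ridge).p
        assert np.abs(a - b).max() < 1e-4

    def test_missing_response_category_rejected(self, fixture_records):
        sub = fixture_records[fixture_records["true_q"] != 3]
        with pytest.raises(BiasParameterError, match=r"\[3\]"):
            fit_multinomial(sub.reset_index(drop=True), 0,
                            with_covariates=False)


@pytest.fixture(scope="module")
def cov_fit():
    coh = generate_cohort(default_config(n=20_000, seed=19))
    fit = fit_multinomial(coh, 0, with_covariates=True)
    return fit, stratum_covariate_means(coh, 0)


class TestAdjustedPredictiveValues:
    def test_rows_sum_to_one_at_random_profiles(self, cov_fit):
        fit, _ = cov_fit
        rng = np.random.default_rng(1)
        for _ in range(100):
            prof = CovariateProfile(age=float(rng.uniform(40, 95)),
                                    sex=float(rng.random()),
                                    rural=float(rng.random()))
            pred = adjusted_predictive_values(fit, prof)
            np.testing.assert_allclose(pred.p.sum(axis=1), 1.0, atol=1e-9)

    def test_delta_and_bootstrap_ci_agree(self, cov_fit):
        fit, prof = cov_fit
        delta = adjusted_predictive_values(fit, prof, ci_method="delta")
        boot = adjusted_predictive_values(fit, prof, ci_method="bootstrap",
                                          n_boot=2000,
                                          rng=np.random.default_rng(7))
        hw_d = (delta.hi - delta.lo) / 2
        hw_b = (boot.hi - boot.lo) / 2
        assert np.abs(hw_d / hw_b - 1).max() < 0.20

    def test_profile_outside_range_warns(self, cov_fit):
        fit, _ = cov_fit
        prof = CovariateProfile(age=200.0, sex=0.5, rural=0.2)
        with pytest.warns(UserWarning, match="outside fitted range"):
            adjusted_predictive_values(fit, prof, covariate_range=(35, 100))


class TestSerialization:
    def test_pv_csv_round_trip(self, tmp_path, validation_tab):
        pvms = {y: crude_predictive_values(validation_tab, y) for y in (0, 1)}
        path = tmp_path / "pv.csv"
        write_pv_csv(pvms, path)
        back = read_pv_csv(path, renormalize=False)
        for y in (0, 1):
            np.testing.assert_allclose(back[y].p, pvms[y].p, atol=1e-12)
            np.testing.assert_allclose(back[y].lo, pvms[y].lo, atol=1e-12)

    def test_published_values_renormalized(self, published_pvms):
        for y in (0, 1):
            np.testing.assert_allclose(published_pvms[y].p.sum(axis=1), 1.0,
                                       atol=1e-12)

    def test_invalid_matrix_rejected(self):
        p = np.full((5, 5), 0.2)
        bad_lo = p + 0.1
        with pytest.raises(BiasParameterError):
            PredictiveValueMatrix(0, p, bad_lo, p)
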