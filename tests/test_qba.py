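"""QBA engine: beta parameterization, sampling, reassignment, Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from income_qba import (
    PredictiveValueMatrix,
    QBAConfig,
    beta_from_interval,
    crude_rr,
    default_config,
    generate_cohort,
    implied_predictive_values,
    reassign_exposure,
    run_qba,
    sample_pv_matrix,
)
from income_qba.qba import QBAError


class TestBetaFromInterval:
    def test_symmetric_closed_form(self):
        spec = beta_from_interval(0.5, 0.304, 0.696)
        assert spec.sd == pytest.approx(0.1)
        assert spec.alpha == pytest.approx(12.0)
        assert spec.beta == pytest.approx(12.0)

    def test_published_cell(self):
        # survived stratum, observed Q1 / true Q1: 31.27 (29.36-33.26)
        spec = beta_from_interval(0.3127, 0.2936, 0.3326)
        assert spec.alpha == pytest.approx(678.649, abs=0.01)
        assert spec.beta == pytest.approx(1491.638, abs=0.01)

    def test_interval_too_wide_rejected(self):
        # implied variance (U-L)^2/3.92^2 must stay below x(1-x)
        with pytest.raises(QBAError, match="too wide"):
            beta_from_interval(0.99, 0.0, 1.0)

    @pytest.mark.parametrize("x", [0.0, 1.0, -0.1, 1.2])
    def test_degenerate_mean_rejected(self, x):
        with pytest.raises(QBAError):
            beta_from_interval(x, 0.1, 0.4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(x=st.floats(0.05, 0.95),
           half=st.floats(0.001, 0.04))
    def test_mean_and_sd_exact(self, x, half):
        """The beta construction reproduces mean x and SD (U-L)/3.92
        exactly (the variance identity is algebraic, not approximate)."""
        spec = beta_from_interval(x, x - half, x + half)
        a, b = spec.alpha, spec.beta
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert abs(mean - x) < 1e-9
        assert abs(np.sqrt(var) - (2 * half) / 3.92) < 1e-9


class TestSamplePVMatrix:
    def test_zero_width_passthrough(self, identity_pv_matrices):
        rng = np.random.default_rng(0)
        out = sample_pv_matrix(identity_pv_matrices[0], rng)
        np.testing.assert_array_equal(out, np.eye(5))

    def test_rows_sum_to_one(self, published_pvms):
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = sample_pv_matrix(published_pvms[0], rng)
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)
            assert (out >= 0).all()

    def test_mean_of_draws_near_point_estimates(self, published_pvms):
        """Renormalization bias is bounded: the mean of many sampled
        matrices stays within 0.01 per cell of the point estimates."""
        rng = np.random.default_rng(2)
        acc = np.zeros((5, 5))
        n = 10_000
        for _ in range(n):
            acc += sample_pv_matrix(published_pvms[0], rng)
        assert np.abs(acc / n - published_pvms[0].p).max() < 0.01


class TestReassignExposure:
    def test_identity_matrices_preserve_observed(self, fixture_records):
        rng = np.random.default_rng(3)
        mats = {0: np.eye(5), 1: np.eye(5)}
        out = reassign_exposure(fixture_records, mats, rng)
        assert (out["adjusted_q"] == out["observed_q"]).all()
        # original fields untouched
        assert (out["true_q"] == fixture_records["true_q"]).all()

    def test_deterministic_row_assigns_single_quintile(self, fixture_records):
        rng = np.random.default_rng(4)
        row1 = np.zeros((5, 5))
        row1[:, 0] = 1.0
        out = reassign_exposure(fixture_records, {0: row1, 1: row1}, rng)
        assert (out["adjusted_q"] == 1).all()

    def test_missing_stratum_matrix_rejected(self, fixture_records):
        with pytest.raises(QBAError, match="stratum 1"):
            reassign_exposure(fixture_records, {0: np.eye(5)},
                              np.random.default_rng(0))

    def test_expectation_matches_analytic(self, fixture_records,
                                          published_pvms, validation_tab):
        """One draw at n ~ 21.6k: the adjusted-quintile x outcome counts sit
        within 3 standard errors of sum_j n_jy * p[j][k]."""
        rng = np.random.default_rng(5)
        mats = {y: published_pvms[y].p for y in (0, 1)}
        out = reassign_exposure(fixture_records, mats, rng)
        for y in (0, 1):
            n_j = validation_tab.stratum(y).sum(axis=1)
            expected = n_j @ published_pvms[y].p
            sub = out[out["died_5y"] == y]
            observed = np.array([(sub["adjusted_q"] == k).sum()
                                 for k in range(1, 6)])
            # variance of a sum of independent categorical draws
            var = (n_j[:, None] * published_pvms[y].p
                   * (1 - published_pvms[y].p)).sum(axis=0)
            assert (np.abs(observed - expected) <= 3 * np.sqrt(var)).all()


class TestRunQBA:
    def test_no_bias_limit(self, fixture_records, identity_pv_matrices):
        """Identity matrices, zero-width intervals, random error off: the
        median equals the naive observed-exposure RR and the SI has width 0."""
        res = run_qba(fixture_records, identity_pv_matrices,
                      QBAConfig(n_iter=5, seed=1, random_error=False))
        naive = crude_rr(1980, 4215, 1680, 4235)
        c = res.contrasts[1]
        assert c.median_rr == pytest.approx(naive.rr, rel=1e-12)
        assert c.si_hi - c.si_lo == 0.0

    def test_parameter_recovery(self):
        """Known mechanism with true RR(Q1 vs Q5) = 1.5: the QBA median
        lands within 0.07 of truth and the SI covers it."""
        cfg = default_config(n=20_000, seed=11,
                             quintile_rr=(1.5, 1.37, 1.19, 1.12, 1.0))
        coh = generate_cohort(cfg)
        ipv = implied_predictive_values(cfg, interval_halfwidth=0.01)
        res = run_qba(coh, ipv, QBAConfig(n_iter=2000, seed=13))
        c = res.contrasts[1]
        assert c.median_rr == pytest.approx(1.5, abs=0.07)
        assert c.si_lo <= 1.5 <= c.si_hi

    def test_seeded_determinism(self, fixture_records, published_pvms):
        cfg = QBAConfig(n_iter=50, seed=99)
        a = run_qba(fixture_records, published_pvms, cfg)
        b = run_qba(fixture_records, published_pvms, cfg)
        for k in (1, 2, 3, 4):
            np.testing.assert_array_equal(a.contrasts[k].log_rr_draws,
                                          b.contrasts[k].log_rr_draws)

    def test_si_width_nondecreasing_in_pv_uncertainty(self, fixture_records,
                                                      published_pvms):
        widths = []
        for scale in (0.5, 1.0, 2.0):
            scaled = {
                y: PredictiveValueMatrix(
                    y, m.p,
                    np.clip(m.p - (m.p - m.lo) * scale, 0, 1),
                    np.clip(m.p + (m.hi - m.p) * scale, 0, 1))
                for y, m in published_pvms.items()
            }
            res = run_qba(fixture_records, scaled,
                          QBAConfig(n_iter=400, seed=7, random_error=False))
            c = res.contrasts[1]
            widths.append(c.si_hi - c.si_lo)
        assert widths[0] < widths[1] < widths[2]

    def test_random_error_widens_si_not_median(self, fixture_records,
                                               published_pvms):
        """Random error inflates the simulation interval but moves the
        median only within Monte Carlo error."""
        on = run_qba(fixture_records, published_pvms,
                     QBAConfig(n_iter=10_000, seed=3, random_error=True))
        off = run_qba(fixture_records, published_pvms,
                      QBAConfig(n_iter=10_000, seed=3, random_error=False))
        c_on, c_off = on.contrasts[1], off.contrasts[1]
        assert (c_on.si_hi - c_on.si_lo) > (c_off.si_hi - c_off.si_lo)
        assert abs(c_on.median_rr - c_off.median_rr) < 0.01

    def test_mean_imputed_table_converges(self, fixture_records,
                                          published_pvms, validation_tab):
        """Across iterations the mean imputed quintile-by-outcome table
        converges to the analytic expectation."""
        seed_seq = np.random.SeedSequence(21)
        acc = {0: np.zeros(5), 1: np.zeros(5)}
        n_rep = 80
        for s in seed_seq.spawn(n_rep):
            rng = np.random.default_rng(s)
            mats = {y: sample_pv_matrix(published_pvms[y], rng) for y in (0, 1)}
            out = reassign_exposure(fixture_records, mats, rng)
            for y in (0, 1):
                sub = out[out["died_5y"] == y]
                acc[y] += np.array([(sub["adjusted_q"] == k).sum()
                                    for k in range(1, 6)])
        for y in (0, 1):
            n_j = validation_tab.stratum(y).sum(axis=1)
            expected = n_j @ published_pvms[y].p
            assert np.abs(acc[y] / n_rep - expected).max() < 0.02 * n_j.sum()

    def test_dirichlet_option_runs(self, fixture_records, published_pvms):
        res = run_qba(fixture_records, published_pvms,
                      QBAConfig(n_iter=30, seed=2, dirichlet_rows=True))
        assert res.contrasts[1].si_lo <= res.contrasts[1].median_rr

    def test_missing_matrix_rejected(self, fixture_records, published_pvms):
        with pytest.raises(QBAError, match="stratum"):
            run_qba(fixture_records, {0: published_pvms[0]},
                    QBAConfig(n_iter=5, seed=0))
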