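"""Recalibration strategies, closed testing and optimism correction."""

import numpy as np
import pytest
from scipy import stats

from asapval import ASAP_MODEL, linear_predictor
from asapval.metrics import c_statistic, calibration_intercept_slope
from asapval.model import RiskModel
from asapval.updating import (
    FitResult,
    bootstrap_optimism,
    closed_test,
    fit_original,
    likelihood_ratio_test,
    recalibrate,
    recalibrate_in_the_large,
    revise,
)

from conftest import scaled_subgroups, simulate_outcomes
from asapval.cohort import generate_cohort


class TestStrategyIdentities:
    """Exact coefficient arithmetic of the three updating transforms."""

    def test_in_the_large_intercept_identity(self):
        m = ASAP_MODEL.shift_intercept(-3.243)
        assert m.intercept == pytest.approx(-10.82011770, abs=1e-8)
        assert m.coefficients == ASAP_MODEL.coefficients  # untouched

    def test_recalibration_coefficient_identity(self):
        m = ASAP_MODEL.rescale(a=-3.577, b=1.192)
        assert m.b_age == pytest.approx(0.0556229754, abs=1e-10)
        assert m.intercept == pytest.approx(-12.60892, abs=5e-6)

    def test_fitted_recalibration_coefficients_are_exact_products(
        self, default_cohort
    ):
        fit = recalibrate(ASAP_MODEL, default_cohort)
        lp = linear_predictor(ASAP_MODEL, default_cohort)
        a, b = calibration_intercept_slope(
            lp, default_cohort["hcc"], "intercept_slope"
        )
        assert fit.model.b_age == b * ASAP_MODEL.b_age
        assert fit.model.b_pivka == b * ASAP_MODEL.b_pivka
        assert fit.model.intercept == b * ASAP_MODEL.intercept + a


class TestFitRecovery:
    def test_in_the_large_null_shift(self, big_selfconsistent_cohort):
        """Data generated from the model itself: fitted intercept update ~0."""
        fit = recalibrate_in_the_large(ASAP_MODEL, big_selfconsistent_cohort)
        assert fit.model.intercept == pytest.approx(ASAP_MODEL.intercept, abs=0.1)
        assert fit.n_free == 1

    def test_in_the_large_recovers_halved_odds(self):
        """Outcomes simulated from the model with its odds halved: the
        fitted intercept shift is ~ -ln 2."""
        cov = generate_cohort(scaled_subgroups(10), seed=21)
        shifted = ASAP_MODEL.shift_intercept(-np.log(2))
        cohort = simulate_outcomes(shifted, cov, seed=22)
        fit = recalibrate_in_the_large(ASAP_MODEL, cohort)
        assert fit.model.intercept - ASAP_MODEL.intercept == pytest.approx(
            -np.log(2), abs=0.1
        )

    def test_recalibration_self_consistency(self, big_selfconsistent_cohort):
        fit = recalibrate(ASAP_MODEL, big_selfconsistent_cohort)
        b = fit.model.b_age / ASAP_MODEL.b_age
        assert b == pytest.approx(1.0, abs=0.1)
        assert fit.n_free == 2

    def test_revision_parameter_recovery(self, big_selfconsistent_cohort):
        """Full refit on ~50,000 simulated patients recovers each true
        coefficient within 3 standard errors."""
        import statsmodels.api as sm
        from asapval.model import _design

        fit = revise(ASAP_MODEL, big_selfconsistent_cohort)
        X = sm.add_constant(_design(big_selfconsistent_cohort))
        res = sm.GLM(
            np.asarray(big_selfconsistent_cohort["hcc"], dtype=float),
            X,
            family=sm.families.Binomial(),
        ).fit()
        se = res.bse
        truth = [ASAP_MODEL.intercept, ASAP_MODEL.b_age, ASAP_MODEL.b_sex,
                 ASAP_MODEL.b_afp, ASAP_MODEL.b_pivka]
        got = [fit.model.intercept, fit.model.b_age, fit.model.b_sex,
               fit.model.b_afp, fit.model.b_pivka]
        for g, t, s in zip(got, truth, se):
            assert abs(g - t) < 3 * s

    def test_nested_deviance_ordering(self, default_cohort):
        d_orig = fit_original(ASAP_MODEL, default_cohort).deviance
        d_itl = recalibrate_in_the_large(ASAP_MODEL, default_cohort).deviance
        d_recal = recalibrate(ASAP_MODEL, default_cohort).deviance
        d_rev = revise(ASAP_MODEL, default_cohort).deviance
        assert d_orig >= d_itl >= d_recal >= d_rev

    def test_df_bookkeeping(self, default_cohort):
        n = len(default_cohort)
        for fn, k in ((fit_original, 0), (recalibrate_in_the_large, 1),
                      (recalibrate, 2), (revise, 5)):
            fit = fn(ASAP_MODEL, default_cohort)
            assert fit.n_free == k
            assert fit.df_resid == n - k
            assert fit.aic == pytest.approx(fit.deviance + 2 * k)

    def test_revalidation_on_own_data_is_calibrated(self, default_cohort):
        """Each updated model re-assessed on its fitting data: intercept 0
        (1e-6); recalibration and revision additionally slope 1."""
        y = default_cohort["hcc"]
        itl = recalibrate_in_the_large(ASAP_MODEL, default_cohort)
        a, _ = calibration_intercept_slope(
            linear_predictor(itl.model, default_cohort), y, "intercept_only"
        )
        assert a == pytest.approx(0.0, abs=1e-6)
        for fit in (recalibrate(ASAP_MODEL, default_cohort),
                    revise(ASAP_MODEL, default_cohort)):
            a, b = calibration_intercept_slope(
                linear_predictor(fit.model, default_cohort), y, "intercept_slope"
            )
            assert a == pytest.approx(0.0, abs=1e-6)
            assert b == pytest.approx(1.0, abs=1e-6)

    def test_discrimination_invariance_across_affine_updates(self, default_cohort):
        y = default_cohort["hcc"]
        c0 = c_statistic(linear_predictor(ASAP_MODEL, default_cohort), y)
        itl = recalibrate_in_the_large(ASAP_MODEL, default_cohort).model
        rec = recalibrate(ASAP_MODEL, default_cohort).model
        assert c_statistic(linear_predictor(itl, default_cohort), y) == c0
        assert c_statistic(linear_predictor(rec, default_cohort), y) == c0


class TestLRT:
    def test_identical_fits(self):
        r = FitResult(ASAP_MODEL, -100.0, 200.0, 1, 1000)
        f = FitResult(ASAP_MODEL, -100.0, 200.0, 5, 1000)
        lrt = likelihood_ratio_test(r, f)
        assert lrt.chi_square == 0.0
        assert lrt.p_value == 1.0
        assert lrt.df == 4

    def test_chi_square_quantile(self):
        r = FitResult(ASAP_MODEL, -101.92, 203.84, 1, 1000)
        f = FitResult(ASAP_MODEL, -100.0, 200.0, 2, 1000)
        lrt = likelihood_ratio_test(r, f)
        assert lrt.chi_square == pytest.approx(3.84, abs=1e-9)
        assert lrt.p_value == pytest.approx(0.050, abs=5e-4)

    def test_negative_statistic_rejected(self):
        r = FitResult(ASAP_MODEL, -99.0, 198.0, 1, 1000)
        f = FitResult(ASAP_MODEL, -100.0, 200.0, 5, 1000)
        with pytest.raises(ValueError):
            likelihood_ratio_test(r, f)


class TestClosedTest:
    def test_intercept_shift_adopts_in_the_large(self):
        """Data built with a pure intercept shift of -3.243: the revision
        beats the original but not the intercept update."""
        cov = generate_cohort(scaled_subgroups(2), seed=31)
        truth = ASAP_MODEL.shift_intercept(-3.243)
        cohort = simulate_outcomes(truth, cov, seed=32)
        result = closed_test(ASAP_MODEL, cohort)
        assert result.adopted == "in_the_large"
        assert result.chain[0].p_value < 0.05
        assert result.chain[1].p_value >= 0.05
        assert result.model.intercept == pytest.approx(truth.intercept, abs=0.5)

    def test_different_slopes_adopt_revision(self):
        """Genuinely different covariate effects at large n force revision."""
        cov = generate_cohort(scaled_subgroups(10), seed=33)
        truth = RiskModel(-9.0, 0.09, -0.6, 0.15, 1.3)
        cohort = simulate_outcomes(truth, cov, seed=34)
        result = closed_test(ASAP_MODEL, cohort)
        assert result.adopted == "revised"

    def test_chain_order_and_labels(self, default_cohort):
        result = closed_test(ASAP_MODEL, default_cohort)
        labels = [l.label for l in result.chain]
        assert labels[0] == "revision vs original"
        assert result.adopted in ("original", "in_the_large", "recalibrated",
                                  "revised")
        assert [l.df for l in result.chain] == [5, 4, 3][: len(labels)]


class TestBootstrapOptimism:
    def test_reproducible_under_seed(self, default_cohort):
        a = bootstrap_optimism(default_cohort, reps=50, seed=5)
        b = bootstrap_optimism(default_cohort, reps=50, seed=5)
        assert a == b

    def test_large_sample_no_overfit(self):
        cov = generate_cohort(scaled_subgroups(5), seed=41)
        cohort = simulate_outcomes(ASAP_MODEL, cov, seed=42)
        res = bootstrap_optimism(cohort, reps=50, seed=43)
        assert abs(res.optimism) < 0.01
        assert res.shrinkage == pytest.approx(1.0, abs=0.05)

    def test_small_sample_shrinks(self):
        """5 free parameters on n=100: bootstrap shrinkage factor < 1."""
        rng = np.random.default_rng(44)
        n = 100
        cov = generate_cohort(
            [s for s in scaled_subgroups(0.1)], seed=45
        ).iloc[:n]
        weak = RiskModel(-2.0, 0.01, -0.2, 0.25, 0.25)
        cohort = simulate_outcomes(weak, cov.reset_index(drop=True), seed=46)
        res = bootstrap_optimism(cohort, reps=60, seed=47)
        assert res.shrinkage < 1.0
        assert res.corrected_c <= res.apparent_c

    def test_minimum_reps_enforced(self, default_cohort):
        with pytest.raises(ValueError):
            bootstrap_optimism(default_cohort, reps=10, seed=0)
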