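"""MR estimators against independent oracles and closed forms."""

import numpy as np
import pytest

from drugmr.errors import InsufficientDataError, StateError
from drugmr.estimators import (classify_significance, cml_ma, egger, ivw,
                               orient_for_inhibition, to_odds_ratio,
                               wald_ratio, weighted_median)

from conftest import make_harmonized, random_valid_instruments


def wls_oracle(bx, by, sy, intercept):
    """Independent weighted-least-squares fit by explicit matrix algebra."""
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx]) if intercept else bx[:, None]
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * by))
    if intercept:
        resid = by - X @ coef
        sigma2 = np.sum(w * resid ** 2) / (len(bx) - 2)
        cov = sigma2 * np.linalg.inv(XtWX)
        return coef, np.sqrt(np.diag(cov))
    return coef, np.sqrt(np.diag(np.linalg.inv(XtWX)))


class TestWaldRatio:
    def test_first_order_arithmetic(self):
        e = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert (e.beta, e.se) == (pytest.approx(0.5), pytest.approx(0.1))

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.02).beta == 0.0

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)

    def test_second_order_close_to_first_for_strong_instruments(self):
        # se_exp/|beta_exp| < 0.05 keeps the two SEs within 5%
        e1 = wald_ratio(0.2, 0.009, 0.1, 0.02)
        e2 = wald_ratio(0.2, 0.009, 0.1, 0.02, second_order=True)
        assert abs(e2.se - e1.se) / e1.se < 0.05


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_harmonized([0.2], [0.01], [0.1], [0.02])
        e = ivw(h)
        w = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert e.beta == pytest.approx(w.beta, abs=1e-15)
        assert e.se == pytest.approx(w.se, abs=1e-15)

    def test_identical_ratios_give_zero_q_and_equal_models(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.01 * np.ones(3), 0.5 * bx, [0.02, 0.03, 0.04])
        e_f = ivw(h, model="fixed")
        e_r = ivw(h, model="multiplicative_random")
        assert e_f.beta == pytest.approx(0.5, abs=1e-12)
        assert e_f.extras["q"] == pytest.approx(0.0, abs=1e-20)
        assert e_f.se == pytest.approx(e_r.se)

    def test_matches_wls_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(3, 40)
            bx = rng.uniform(0.02, 0.3, n)
            sy = rng.uniform(0.01, 0.2, n)
            by = rng.normal(0.4 * bx, sy)
            h = make_harmonized(bx, 0.001 * np.ones(n), by, sy)
            e = ivw(h, model="fixed")
            coef, se = wls_oracle(bx, by, sy, intercept=False)
            assert e.beta == pytest.approx(coef[0], abs=1e-10)
            assert e.se == pytest.approx(se[0], abs=1e-10)

    def test_recovers_synthetic_truth(self):
        h = random_valid_instruments(np.random.default_rng(42), n=50, theta=0.5)
        e = ivw(h)
        assert abs(e.beta - 0.5) < 2 * e.se

    def test_empty_input_rejected(self):
        h = make_harmonized([], [], [], [])
        with pytest.raises(InsufficientDataError):
            ivw(h)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.linspace(0.05, 0.3, 6)
        by = 0.02 + 0.5 * bx
        h = make_harmonized(bx, 0.001 * np.ones(6), by, 0.02 * np.ones(6))
        e = egger(h)
        assert e.beta == pytest.approx(0.5, abs=1e-10)
        assert e.egger_intercept == pytest.approx(0.02, abs=1e-10)
        assert e.extras["q"] == pytest.approx(0.0, abs=1e-16)

    def test_matches_wls_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(4, 30)
            bx = rng.uniform(0.02, 0.3, n)  # positive, as Egger orients
            sy = rng.uniform(0.01, 0.2, n)
            by = rng.normal(0.03 + 0.4 * bx, sy)
            h = make_harmonized(bx, 0.001 * np.ones(n), by, sy)
            e = egger(h)
            coef, se = wls_oracle(bx, by, sy, intercept=True)
            assert e.beta == pytest.approx(coef[1], abs=1e-10)
            assert e.egger_intercept == pytest.approx(coef[0], abs=1e-10)
            assert e.se == pytest.approx(se[1], rel=1e-8)

    def test_planted_directional_pleiotropy_recovered(self):
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(900 + seed)
            n = 25
            bx = rng.uniform(0.05, 0.15, n)
            sy = rng.uniform(0.02, 0.05, n)
            by = 0.05 + sy * rng.standard_normal(n)  # theta = 0, intercept 0.05
            h = make_harmonized(bx, 0.002 * np.ones(n), by, sy)
            e = egger(h)
            covered += abs(e.egger_intercept - 0.05) <= 2 * e.egger_intercept_se
        assert covered >= 80

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientDataError):
            egger(make_harmonized([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.02] * 2))


class TestWeightedMedian:
    def test_equal_weights_median_ratio(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.5, 0.9])
        h = make_harmonized(bx, 0.001 * np.ones(3), by, np.ones(3))
        assert weighted_median(h).beta == pytest.approx(0.5)

    def test_bit_reproducible_with_fixed_seed(self):
        h = random_valid_instruments(np.random.default_rng(5), n=20)
        a = weighted_median(h, seed=7)
        b = weighted_median(h, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_robust_to_forty_percent_balanced_pleiotropy(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(500 + seed)
            n = 20
            bx = rng.uniform(0.05, 0.15, n)
            sy = rng.uniform(0.03, 0.08, n)
            by = 0.5 * bx + sy * rng.standard_normal(n)
            bad = rng.choice(n, 8, replace=False)
            by[bad] += rng.choice([-1, 1], 8) * rng.uniform(2, 6, 8) * sy[bad]
            e = weighted_median(make_harmonized(bx, 0.002 * np.ones(n), by, sy),
                                seed=seed)
            hits += abs(e.beta - 0.5) <= 2 * e.se
        assert hits >= 75


class TestCmlMa:
    def test_reduces_to_fixed_ivw_when_no_invalid_allowed(self):
        h = random_valid_instruments(np.random.default_rng(6), n=15)
        e_cml = cml_ma(h, max_invalid=0)
        e_ivw = ivw(h, model="fixed")
        assert e_cml.beta == pytest.approx(e_ivw.beta, abs=1e-8)
        assert e_cml.se == pytest.approx(e_ivw.se, abs=1e-8)

    def test_bic_weights_sum_to_one(self):
        h = random_valid_instruments(np.random.default_rng(8), n=12)
        e = cml_ma(h)
        assert sum(e.extras["bic_weights"]) == pytest.approx(1.0, abs=1e-12)

    def test_planted_outliers_selected(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 30
            bx = rng.uniform(0.05, 0.15, n)
            sy = rng.uniform(0.03, 0.08, n)
            by = 0.5 * bx + sy * rng.standard_normal(n)
            planted = [3, 11, 22]
            for i in planted:
                by[i] += 8 * sy[i]
            e = cml_ma(make_harmonized(bx, 0.002 * np.ones(n), by, sy))
            hits += set(planted) <= set(e.extras["invalid_indices"])
        assert hits >= 90


class TestOrientationAndOR:
    def test_orientation_negates_and_swaps_ci(self):
        e = ivw(make_harmonized([0.1], [0.01], [0.09], [0.02]))
        o = orient_for_inhibition(e)
        assert o.beta == -e.beta
        assert (o.ci_low, o.ci_high) == (-e.ci_high, -e.ci_low)
        assert o.pval == e.pval

    def test_double_orientation_guarded(self):
        e = ivw(make_harmonized([0.1], [0.01], [0.09], [0.02]))
        with pytest.raises(StateError):
            orient_for_inhibition(orient_for_inhibition(e))

    def test_involution_up_to_guard(self):
        import dataclasses
        e = ivw(make_harmonized([0.1], [0.01], [0.09], [0.02]))
        o = orient_for_inhibition(e)
        back = orient_for_inhibition(dataclasses.replace(o, oriented_for_inhibition=False))
        assert (back.beta, back.ci_low, back.ci_high) == (e.beta, e.ci_low, e.ci_high)

    def test_or_identity_at_zero(self):
        assert to_odds_ratio(0.0, 0.0, 0.0) == (1.0, 1.0, 1.0)

    def test_ci_must_bracket_estimate(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.5, 0.6, 0.7)


class TestSignificanceCall:
    def test_bonferroni_significant(self):
        c = classify_significance(1e-4, 9, [-0.2, -0.3, -0.25])
        assert c.level == "significant" and c.direction_consistent

    def test_suggestive_band(self):
        assert classify_significance(0.014, 9, [-1, -1, -1]).level == "suggestive"

    def test_inconsistent_directions_null_despite_small_p(self):
        assert classify_significance(0.01, 9, [0.2, -0.3, -0.1]).level == "null"

    def test_empty_directions_rejected(self):
        with pytest.raises(ValueError):
            classify_significance(0.01, 9, [])
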