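"""MR estimators: hand-computed values, independent oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrpath import (InsufficientInstrumentsError, UndefinedRatioError, egger,
                    ivw, mode_estimate, to_odds_ratio, wald_ratio,
                    weighted_median)
from mrpath.estimators import all_estimates, ratio_estimates
from conftest import make_h, strong_null_instruments
from oracles import ivw_by_sums, kde_mode_by_grid, weighted_median_by_scan, wls_by_statsmodels


class TestWaldRatio:
    def test_null_outcome_gives_zero(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.01).beta == 0.0

    def test_hand_computation(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


class TestIvw:
    def test_single_instrument_reduces_to_wald(self):
        h = make_h([0.1], [0.01], [0.05], [0.01])
        est = ivw(h, model="fixed")
        ref = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_two_snp_hand_computed_weighted_sums(self):
        # w = {100, 100}; beta = 110/200
        h = make_h([0.1, 0.2], [0.01, 0.01], [0.05, 0.12], [0.01, 0.02])
        assert ivw(h, model="fixed").beta == pytest.approx(0.55)

    def test_homogeneous_ratios_random_equals_fixed(self):
        h = make_h([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.01] * 3)
        assert ivw(h, model="random").se == pytest.approx(ivw(h, model="fixed").se)

    def test_random_se_never_below_fixed(self, rng):
        for r in range(20):
            h = strong_null_instruments(rng, j=10)
            assert ivw(h, model="random").se >= ivw(h, model="fixed").se - 1e-15

    def test_random_model_needs_two(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_h([0.1], [0.01], [0.05], [0.01]), model="random")

    def test_matches_explicit_sum_oracle(self, rng):
        for _ in range(5):
            h = strong_null_instruments(rng, j=int(rng.integers(2, 13)), theta=0.3)
            beta, se = ivw_by_sums(h.beta_exp, h.se_exp, h.beta_out, h.se_out)
            est = ivw(h, model="fixed")
            assert est.beta == pytest.approx(beta, abs=1e-12)
            assert est.se == pytest.approx(se, abs=1e-12)


class TestEgger:
    def test_exact_linear_data_recovered(self, exact_linear_h):
        res = egger(exact_linear_h)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-12)

    def test_agrees_with_generic_wls_oracle(self, rng):
        for _ in range(5):
            h = strong_null_instruments(rng, j=int(rng.integers(3, 13)), theta=0.2)
            res = egger(h)
            icpt, slope = wls_by_statsmodels(h.beta_exp, h.beta_out, h.se_out)
            assert res.intercept == pytest.approx(icpt, abs=1e-10)
            assert res.slope.beta == pytest.approx(slope, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_h([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))

    def test_slope_equals_ivw_when_intercept_zero(self):
        # through-origin data with equal weights: fitted intercept is 0 and
        # the Egger slope coincides with IVW
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_h(bx, [0.01] * 4, 0.5 * bx, [0.02] * 4)
        res = egger(h)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope.beta == pytest.approx(ivw(h, model="fixed").beta, abs=1e-12)


class TestWeightedMedian:
    def test_symmetric_midpoint_hits_middle_ratio(self):
        # equal weights, ratios {0.4, 0.5, 0.9}: midpoints {1/6, 1/2, 5/6}
        h = make_h([0.1, 0.1, 0.1], [0.01] * 3, [0.04, 0.05, 0.09], [0.01] * 3)
        assert weighted_median(h, n_boot=100, seed=1).beta == pytest.approx(0.5)

    def test_degenerate_distribution(self):
        h = make_h([0.1, 0.2, 0.4], [0.001] * 3, [0.05, 0.10, 0.20], [0.0001] * 3)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)
        assert est.se < 0.01

    def test_matches_scan_oracle(self, rng):
        for _ in range(5):
            h = strong_null_instruments(rng, j=int(rng.integers(3, 13)), theta=0.3)
            theta, var = ratio_estimates(h)
            ref = weighted_median_by_scan(list(theta), list(1 / var))
            est = weighted_median(h, n_boot=100, seed=2)
            assert est.beta == pytest.approx(ref, abs=1e-12)

    def test_robust_to_minority_pleiotropy(self, rng):
        """With 30% invalid instruments carrying large pleiotropy, the
        weighted median stays closer to truth than IVW on average."""
        err_med, err_ivw = [], []
        for r in range(120):
            h = strong_null_instruments(rng, j=10, theta=0.3)
            bad = slice(0, 3)
            bo = h.beta_out.copy()
            bo[bad] += 0.5  # directional pleiotropy on 3/10 instruments
            h2 = make_h(h.beta_exp, h.se_exp, bo, h.se_out)
            err_med.append(abs(weighted_median(h2, n_boot=100, seed=r).beta - 0.3))
            err_ivw.append(abs(ivw(h2, model="fixed").beta - 0.3))
        assert np.mean(err_med) < np.mean(err_ivw)


class TestModeEstimate:
    def test_point_mass_returns_common_ratio(self):
        h = make_h([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.01] * 3)
        assert mode_estimate(h, n_boot=100, seed=1).beta == pytest.approx(0.5)

    def test_majority_cluster_dominates(self):
        h = make_h([0.1, 0.1, 0.1, 0.1], [0.01] * 4,
                   [0.05, 0.05, 0.05, 0.20], [0.01] * 4)
        est = mode_estimate(h, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(3):
            h = strong_null_instruments(rng, j=int(rng.integers(4, 13)), theta=0.3)
            theta, var = ratio_estimates(h)
            ref_simple = kde_mode_by_grid(theta, np.ones_like(theta))
            ref_weight = kde_mode_by_grid(theta, 1 / var)
            assert mode_estimate(h, weighted=False, n_boot=100, seed=3).beta == \
                pytest.approx(ref_simple, abs=1e-10)
            assert mode_estimate(h, weighted=True, n_boot=100, seed=3).beta == \
                pytest.approx(ref_weight, abs=1e-10)

    def test_weighted_equals_simple_under_equal_weights(self):
        h = make_h([0.1, 0.1, 0.1, 0.1], [0.01] * 4,
                   [0.04, 0.05, 0.06, 0.12], [0.01] * 4)
        simple = mode_estimate(h, weighted=False, n_boot=100, seed=4)
        weighted = mode_estimate(h, weighted=True, n_boot=100, seed=4)
        assert simple.beta == pytest.approx(weighted.beta, abs=1e-12)


class TestToOddsRatio:
    def test_null_effect(self):
        or_v, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_v == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric in log space

    def test_zero_variance_collapse(self):
        assert to_odds_ratio(np.log(2), 0.0) == pytest.approx((2, 2, 2))

    def test_reported_triple_roundtrip(self):
        # log-OR 2.1306 with SE 0.7986 renders as 8.42 (1.76-40.28)
        or_v, lo, hi = to_odds_ratio(2.1306, 0.7986)
        assert round(or_v, 2) == 8.42
        assert round(lo, 2) == 1.76
        assert round(hi, 2) == 40.28


class TestEstimatorInvariances:
    def test_all_agree_on_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        h = make_h(bx, [0.01] * 4, 0.7 * bx, [0.01] * 4)
        for est in all_estimates(h, seed=0, n_boot=100):
            assert est.beta == pytest.approx(0.7, abs=1e-9), est.method

    @given(st.permutations(list(range(8))))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_order_invariance(self, perm):
        rng = np.random.default_rng(99)
        h = strong_null_instruments(rng, j=8, theta=0.3)
        hp = h.subset(np.array(perm))
        assert ivw(hp, model="random").beta == pytest.approx(ivw(h, model="random").beta, abs=1e-12)
        assert egger(hp).slope.beta == pytest.approx(egger(h).slope.beta, abs=1e-10)
        assert weighted_median(hp, n_boot=100, seed=0).beta == \
            pytest.approx(weighted_median(h, n_boot=100, seed=0).beta, abs=1e-12)

    def test_ci_contains_beta(self, rng):
        h = strong_null_instruments(rng, j=10, theta=0.3)
        for est in all_estimates(h, seed=0, n_boot=100):
            assert est.ci_low <= est.beta <= est.ci_high
            assert est.or_value == pytest.approx(np.exp(est.beta))
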