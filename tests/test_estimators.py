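"""IVW, MR-Egger and weighted-median estimators against independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrscreen.errors import DegenerateDesignError, InsufficientInstrumentsError
from mrscreen.harmonize import harmonized_from_arrays
from mrscreen.mr_estimators import (
    _weighted_median,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)
from tests.conftest import random_harmonized_set


def hset(gamma, Gamma, se_Gamma, se_gamma=None, outcome_type="continuous"):
    gamma = np.asarray(gamma, dtype=float)
    if se_gamma is None:
        se_gamma = np.full_like(gamma, 0.01)
    return harmonized_from_arrays(gamma, se_gamma, Gamma, se_Gamma,
                                  outcome_type=outcome_type)


class TestWaldRatio:
    def test_direct_ratio_and_delta_method_se(self):
        h = hset([0.1], [0.05], [0.02])
        r = wald_ratio(h.snps.iloc[0])
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_null_outcome_effect(self):
        r = wald_ratio(hset([0.1], [0.0], [0.02]).snps.iloc[0])
        assert r.beta == 0.0 and r.pval == 1.0

    def test_joint_sign_flip_invariance(self):
        a = wald_ratio(hset([0.1], [0.05], [0.02]).snps.iloc[0])
        b = wald_ratio(hset([-0.1], [-0.05], [0.02]).snps.iloc[0])
        assert a.beta == b.beta and a.se == b.se

    def test_zero_gamma_is_hard_error(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(hset([0.0], [0.05], [0.02]).snps.iloc[0])


class TestIvw:
    def test_identical_ratios_recovered_exactly_with_unit_scale(self):
        h = hset([0.1, 0.2], [0.05, 0.10], [0.02, 0.03])
        r = ivw(h)
        assert r.beta == pytest.approx(0.5, rel=1e-14)
        # zero residuals => phi floor at 1: se equals fixed-effect se
        fe_se = 1 / np.sqrt(np.sum(np.array([0.1, 0.2]) ** 2 / np.array([0.02, 0.03]) ** 2))
        assert r.se == pytest.approx(fe_se, rel=1e-14)

    def test_single_snp_delegates_to_wald_ratio(self):
        h = hset([0.1], [0.05], [0.02])
        r = ivw(h)
        w = wald_ratio(h.snps.iloc[0])
        assert (r.beta, r.se, r.pval) == (w.beta, w.se, w.pval)
        assert r.method == "ivw"

    def test_matches_weighted_regression_through_origin(self, rng):
        h = random_harmonized_set(rng, 10)
        r = ivw(h)
        w = 1 / h.se_Gamma() ** 2
        fit = sm.WLS(h.Gamma(), h.gamma(), weights=w).fit()
        assert r.beta == pytest.approx(fit.params[0], rel=1e-10)
        scale_floor = max(1.0, np.sqrt(fit.scale))
        assert r.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale) * scale_floor,
                                     rel=1e-10)

    def test_equals_weighted_average_of_wald_ratios(self, rng):
        h = random_harmonized_set(rng, 15)
        r = ivw(h)
        theta = h.Gamma() / h.gamma()
        w = h.gamma() ** 2 / h.se_Gamma() ** 2
        assert r.beta == pytest.approx(np.sum(w * theta) / np.sum(w), rel=1e-12)

    def test_fixed_effect_variant_never_inflates(self, rng):
        h = random_harmonized_set(rng, 12)
        assert ivw(h, random_effects=False).se <= ivw(h, random_effects=True).se

    def test_binary_outcome_gets_exact_odds_ratio_fields(self, rng):
        h = random_harmonized_set(rng, 8, outcome_type="binary")
        r = ivw(h)
        assert r.or_ == np.exp(r.beta)
        assert r.or_low == np.exp(r.ci_low)
        assert r.or_high == np.exp(r.ci_high)


class TestEgger:
    def test_exact_line_recovered(self):
        gamma = np.array([0.05, 0.1, 0.15, 0.2])
        Gamma = 0.02 + 0.3 * gamma
        r = egger(hset(gamma, Gamma, [0.01, 0.01, 0.02, 0.02]))
        assert r.intercept == pytest.approx(0.02, rel=1e-10)
        assert r.beta == pytest.approx(0.3, rel=1e-10)
        # exact fit => residual scale floored at 1
        w = 1 / np.array([0.01, 0.01, 0.02, 0.02]) ** 2
        sw, swx, swxx = w.sum(), (w * gamma).sum(), (w * gamma**2).sum()
        det = sw * swxx - swx**2
        assert r.se == pytest.approx(np.sqrt(sw / det), rel=1e-10)

    def test_collinear_design_raises(self):
        with pytest.raises(DegenerateDesignError):
            egger(hset([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], [0.01, 0.01, 0.01]))

    def test_too_few_instruments_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(hset([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))

    def test_matches_generic_weighted_linear_regression(self, rng):
        h = random_harmonized_set(rng, 15)
        r = egger(h)
        g, G = h.gamma(), h.Gamma()
        flip = np.where(g < 0, -1.0, 1.0)
        g, G = g * flip, G * flip
        X = sm.add_constant(g)
        fit = sm.WLS(G, X, weights=1 / h.se_Gamma() ** 2).fit()
        assert r.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert r.beta == pytest.approx(fit.params[1], rel=1e-10)
        floor = max(1.0, np.sqrt(fit.scale))
        assert r.intercept_se == pytest.approx(
            fit.bse[0] / np.sqrt(fit.scale) * floor, rel=1e-10)
        assert r.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * floor, rel=1e-10)

    def test_agrees_with_ivw_without_pleiotropy(self, rng):
        # large homogeneous set: slope ~ IVW slope within Monte-Carlo error
        n = 200
        gamma = rng.uniform(0.05, 0.3, n)
        Gamma = 0.25 * gamma + rng.normal(0, 0.002, n)
        h = hset(gamma, Gamma, np.full(n, 0.002))
        assert egger(h).beta == pytest.approx(ivw(h).beta, abs=0.01)

    def test_pvalues_use_t_distribution(self, rng):
        h = random_harmonized_set(rng, 6)
        r = egger(h)
        expected = 2 * stats.t.sf(abs(r.beta / r.se), 4)
        assert r.pval == pytest.approx(expected, rel=1e-12)


def brute_weighted_median(theta, w):
    """Loop-based oracle: sort, accumulate midpoint weights, interpolate."""
    pairs = sorted(zip(theta, w))
    total = sum(w for _, w in pairs)
    cum = 0.0
    s, th = [], []
    for t, wi in pairs:
        s.append((cum + wi / 2) / total)
        th.append(t)
        cum += wi
    if 0.5 <= s[0]:
        return th[0]
    for i in range(1, len(s)):
        if s[i] >= 0.5:
            frac = (0.5 - s[i - 1]) / (s[i] - s[i - 1])
            return th[i - 1] + frac * (th[i] - th[i - 1])
    return th[-1]


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = hset([0.1, 0.1, 0.1], [0.01, 0.05, 0.09], [0.01, 0.01, 0.01])
        r = weighted_median(h, n_boot=100, seed=1)
        assert r.beta == pytest.approx(0.5)

    def test_identical_ratios_and_vanishing_se(self):
        gamma = np.array([0.1, 0.2, 0.3])
        h = harmonized_from_arrays(gamma, np.full(3, 1e-8), 0.7 * gamma, np.full(3, 1e-8))
        r = weighted_median(h, n_boot=200, seed=2)
        assert r.beta == pytest.approx(0.7, rel=1e-6)
        assert r.se < 1e-6

    def test_matches_brute_force_oracle(self, rng):
        h = random_harmonized_set(rng, 11)
        r = weighted_median(h, n_boot=100, seed=3)
        theta = h.Gamma() / h.gamma()
        w = h.gamma() ** 2 / h.se_Gamma() ** 2
        assert r.beta == pytest.approx(brute_weighted_median(theta, w), rel=1e-12)

    def test_bootstrap_reproducible_bit_for_bit(self, rng):
        h = random_harmonized_set(rng, 11)
        a = weighted_median(h, n_boot=300, seed=77)
        b = weighted_median(h, n_boot=300, seed=77)
        assert a.se == b.se and a.pval == b.pval

    def test_seed_is_mandatory(self, rng):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(random_harmonized_set(rng, 5), n_boot=100, seed=None)

    def test_majority_valid_weight_converges_to_true_ratio(self, rng):
        # 60% of weight on ratio 0.4, 40% on a contaminated ratio, tiny SEs
        gamma = np.concatenate([np.full(6, 0.2), np.full(4, 0.2)])
        Gamma = np.concatenate([0.4 * np.full(6, 0.2), 1.5 * np.full(4, 0.2)])
        h = harmonized_from_arrays(gamma, np.full(10, 1e-6), Gamma, np.full(10, 1e-6))
        r = weighted_median(h, n_boot=100, seed=5)
        assert r.beta == pytest.approx(0.4, abs=1e-6)

    def test_estimate_bounded_by_extreme_ratios(self, rng):
        for trial in range(20):
            h = random_harmonized_set(np.random.default_rng(trial), 7)
            theta = h.Gamma() / h.gamma()
            w = h.gamma() ** 2 / h.se_Gamma() ** 2
            m = _weighted_median(theta, w)
            assert theta.min() - 1e-12 <= m <= theta.max() + 1e-12
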