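"""Estimator correctness against independent oracles, plus shared invariants."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrpath.estimators import (beta_to_or, ivw, mode_estimate, mr_egger,
                               wald_ratio, weighted_median)
from mrpath.exceptions import EstimationError
from mrpath.sumstats import HarmonizedSet

from conftest import make_hs


def negate_outcome(hs):
    bx, sx, by, sy = hs.arrays()
    return HarmonizedSet.from_arrays(bx, sx, -by, sy)


class TestWaldRatio:
    def test_direct_division(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).beta == 0.0

    def test_sign_flip_invariance(self):
        a = wald_ratio(0.1, 0.01, 0.05, 0.02)
        b = wald_ratio(-0.1, 0.01, -0.05, 0.02)
        assert (a.beta, a.se) == (pytest.approx(b.beta), pytest.approx(b.se))

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_single_pair_equals_wald(self):
        hs = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        est = ivw(hs)
        wr = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(wr.beta)
        assert est.se == pytest.approx(wr.se)

    def test_homogeneous_ratios_fixed_equals_random(self):
        bx = np.array([0.1, 0.2, 0.05])
        hs = HarmonizedSet.from_arrays(bx, bx * 0.1, 0.3 * bx, [0.02] * 3)
        fixed = ivw(hs, mode="fixed")
        mre = ivw(hs, mode="multiplicative_random")
        assert fixed.beta == pytest.approx(0.3)
        assert fixed.extras["q_stat"] == pytest.approx(0.0, abs=1e-20)
        assert fixed.se == pytest.approx(mre.se)

    def test_matches_wls_through_origin_oracle(self, hs20):
        """Slope and model se agree with statsmodels WLS (no constant,
        weights 1/se_out^2) to 1e-10."""
        bx, _, by, sy = hs20.arrays()
        fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        fixed = ivw(hs20, mode="fixed")
        assert fixed.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels reports a residual-scaled se; the fixed-effect se is
        # the unscaled (sigma = 1) version
        unscaled_se = fit.bse[0] / np.sqrt(fit.mse_resid)
        assert fixed.se == pytest.approx(unscaled_se, abs=1e-10)
        mre = ivw(hs20, mode="multiplicative_random")
        k = hs20.n_snps
        expected_scale = max(1.0, np.sqrt(fixed.extras["q_stat"] / (k - 1)))
        assert mre.se == pytest.approx(fixed.se * expected_scale, abs=1e-12)

    def test_empty_set_rejected(self):
        hs = HarmonizedSet.from_arrays([], [], [], [])
        with pytest.raises(EstimationError):
            ivw(hs)


class TestEgger:
    def test_exact_fit_recovers_line(self):
        bx = np.linspace(0.05, 0.3, 8)
        by = 0.02 + 0.4 * bx
        hs = HarmonizedSet.from_arrays(bx, bx * 0.05, by, [0.02] * 8)
        est = mr_egger(hs)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.extras["intercept"] == pytest.approx(0.02, abs=1e-12)
        assert est.extras["residual_scale"] == pytest.approx(1.0)  # lower bound

    def test_two_pairs_insufficient(self):
        hs = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.05, 0.1],
                                       [0.02] * 2)
        with pytest.raises(EstimationError, match="insufficient SNPs for Egger"):
            mr_egger(hs)

    def test_matches_weighted_ols_oracle(self, hs20):
        """Slope, intercept and (scaled) t-based ses agree with statsmodels
        WLS-with-constant to 1e-10 after orienting exposure betas positive."""
        bx, _, by, sy = hs20.arrays()
        flip = np.sign(bx)
        x, y = bx * flip, by * flip
        fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / sy**2).fit()
        est = mr_egger(hs20)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales by sqrt(mse_resid); ours bounds the scale below by 1
        scale = max(1.0, np.sqrt(fit.mse_resid)) / np.sqrt(fit.mse_resid)
        assert est.se == pytest.approx(fit.bse[1] * scale, abs=1e-10)
        assert est.extras["intercept_se"] == pytest.approx(
            fit.bse[0] * scale, abs=1e-10)

    def test_orientation_invariance(self, hs20):
        """Flipping the sign of individual pairs (both betas) leaves the
        Egger fit unchanged."""
        bx, sx, by, sy = hs20.arrays()
        rng = np.random.default_rng(3)
        s = rng.choice([-1.0, 1.0], size=len(bx))
        flipped = HarmonizedSet.from_arrays(bx * s, sx, by * s, sy)
        a, b = mr_egger(hs20), mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.extras["intercept"] == pytest.approx(b.extras["intercept"])


def definitional_weighted_median(ratios, weights):
    """Oracle: cumulative-normalized-weight definition evaluated directly."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    cw = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cw, r))


class TestWeightedMedian:
    def test_equal_weights_reduce_to_plain_median(self):
        bx = np.ones(5)
        by = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        hs = HarmonizedSet.from_arrays(bx, bx * 0.01, by, np.ones(5))
        est = weighted_median(hs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_order_invariance_and_seed_reproducibility(self, hs20):
        est = weighted_median(hs20, n_boot=200, seed=42)
        perm = np.random.default_rng(0).permutation(hs20.n_snps)
        bx, sx, by, sy = hs20.arrays()
        ids = hs20.pairs["snp_id"].to_numpy()
        hs_perm = HarmonizedSet.from_arrays(bx[perm], sx[perm], by[perm],
                                            sy[perm], snp_ids=ids[perm])
        est_p = weighted_median(hs_perm, n_boot=200, seed=42)
        assert est_p.beta == pytest.approx(est.beta)
        assert est_p.se == pytest.approx(est.se)

    def test_dominant_weight_matches_definition(self):
        bx = np.ones(3)
        by = np.array([0.25, 0.8, 1.4])
        sy = np.array([0.1 / np.sqrt(98), 0.1, 0.1])  # weights ~ (0.98, .01, .01)
        hs = HarmonizedSet.from_arrays(bx, bx * 0.001, by, sy)
        est = weighted_median(hs, n_boot=50, seed=2)
        w = (bx / sy) ** 2
        expected = definitional_weighted_median(by, w)
        assert est.beta == pytest.approx(expected, abs=1e-12)
        assert abs(est.beta - 0.25) < 0.1  # in the dominant SNP's neighborhood

    def test_matches_definition_on_random_fixture(self, hs20):
        bx, _, by, sy = hs20.arrays()
        expected = definitional_weighted_median(by / bx, (bx / sy) ** 2)
        est = weighted_median(hs20, n_boot=50, seed=3)
        assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_requires_three_pairs(self):
        hs = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.1, 0.2],
                                       [0.02] * 2)
        with pytest.raises(EstimationError):
            weighted_median(hs, seed=1)


def grid_search_mode(ratios, weights, h, step=1e-4):
    """Oracle: brute-force maximization of the weighted kernel density over
    [min, max] at a fixed step."""
    grid = np.arange(ratios.min(), ratios.max() + step, step)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = np.exp(-0.5 * z**2) @ (weights / weights.sum())
    return float(grid[np.argmax(dens)])


class TestModes:
    def test_degenerate_distribution_returns_common_ratio(self):
        bx = np.ones(4)
        hs = HarmonizedSet.from_arrays(bx, bx * 0.01, 0.25 * bx, [0.02] * 4)
        est = mode_estimate(hs, weighted=False, n_boot=50, seed=4)
        assert est.beta == pytest.approx(0.25)

    def test_majority_cluster_wins_over_mean(self):
        bx = np.ones(4)
        by = np.array([0.3, 0.3, 0.3, 1.5])
        hs = HarmonizedSet.from_arrays(bx, bx * 0.01, by, [0.05] * 4)
        est = mode_estimate(hs, weighted=False, n_boot=50, seed=5)
        assert abs(est.beta - 0.3) < 0.1
        assert abs(est.beta - by.mean()) > 0.1

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_grid_search_oracle(self, hs20, weighted):
        from mrpath.estimators import _mode_bandwidth
        bx, _, by, sy = hs20.arrays()
        ratios = by / bx
        weights = (bx / sy) ** 2 if weighted else np.ones(len(bx))
        h = _mode_bandwidth(ratios, 1.0)
        expected = grid_search_mode(ratios, weights, h)
        est = mode_estimate(hs20, weighted=weighted, n_boot=50, seed=6)
        assert est.beta == pytest.approx(expected, abs=1e-3)

    def test_requires_three_pairs(self):
        hs = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.1, 0.2],
                                       [0.02] * 2)
        with pytest.raises(EstimationError):
            mode_estimate(hs, seed=1)


class TestBetaToOR:
    def test_null_effect_gives_unit_or(self):
        or_, lo, hi = beta_to_or(0.0, 0.1)
        assert or_ == 1.0 and lo < 1.0 < hi

    def test_published_total_effect_matches_in_text_or(self):
        # log-odds -0.7951 corresponds to the printed OR 0.452
        assert beta_to_or(-0.7951, 0.1)[0] == pytest.approx(0.452, abs=5e-4)

    def test_published_leg_effect_matches_in_text_or(self):
        assert beta_to_or(-0.1215, 0.1)[0] == pytest.approx(0.886, abs=5e-4)

    def test_ci_is_exponentiated_normal_interval(self):
        or_, lo, hi = beta_to_or(0.3, 0.05)
        assert lo == pytest.approx(np.exp(0.3 - 1.96 * 0.05))
        assert hi == pytest.approx(np.exp(0.3 + 1.96 * 0.05))


class TestSharedInvariants:
    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median",
                                        "simple_mode", "weighted_mode"])
    def test_equivariance_negating_outcome_negates_estimate(self, hs20, method):
        def run(hs):
            if method == "ivw":
                return ivw(hs).beta
            if method == "egger":
                return mr_egger(hs).beta
            if method == "weighted_median":
                return weighted_median(hs, n_boot=50, seed=7).beta
            return mode_estimate(hs, weighted=method == "weighted_mode",
                                 n_boot=50, seed=7).beta
        assert run(negate_outcome(hs20)) == pytest.approx(-run(hs20), abs=1e-6)

    def test_homogeneous_ratios_all_methods_agree(self, hs_homogeneous):
        hs = hs_homogeneous
        assert ivw(hs).beta == pytest.approx(0.3)
        egger = mr_egger(hs)
        assert egger.beta == pytest.approx(0.3, abs=1e-10)
        assert egger.extras["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert weighted_median(hs, n_boot=50, seed=8).beta == pytest.approx(0.3)
        assert mode_estimate(hs, weighted=False, n_boot=50,
                             seed=8).beta == pytest.approx(0.3, abs=1e-6)
        assert mode_estimate(hs, weighted=True, n_boot=50,
                             seed=8).beta == pytest.approx(0.3, abs=1e-6)
        assert ivw(hs).extras["q_stat"] == pytest.approx(0.0, abs=1e-18)

    def test_ci_and_or_fields_consistent(self, hs20):
        est = ivw(hs20)
        assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se)
        assert est.ci_high == pytest.approx(est.beta + 1.96 * est.se)
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low <= est.beta <= est.ci_high


class TestRobustnessSimulation:
    def test_weighted_median_resists_directional_pleiotropy(self):
        """With 30% of instruments carrying large directional pleiotropy,
        the weighted median's bias stays below half the IVW bias."""
        rng = np.random.default_rng(1234)
        true = 0.3
        reps = 300
        k = 15
        ivw_err = np.empty(reps)
        wm_err = np.empty(reps)
        for i in range(reps):
            bx = rng.uniform(0.05, 0.2, k)
            sx = np.full(k, 0.005)
            sy = np.full(k, 0.02)
            pleio = np.zeros(k)
            pleio[: int(0.3 * k)] = 0.08  # large, all same direction
            by = true * bx + pleio + rng.normal(0, sy)
            hs = HarmonizedSet.from_arrays(bx + rng.normal(0, sx), sx, by, sy)
            ivw_err[i] = ivw(hs).beta - true
            wm_err[i] = definitional_weighted_median(
                hs.arrays()[2] / hs.arrays()[0],
                (hs.arrays()[0] / sy) ** 2) - true
        assert abs(wm_err.mean()) < 0.5 * abs(ivw_err.mean())
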