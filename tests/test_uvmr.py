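import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate import (EstimationError, MRConfig, SimulationConfig,
                       cochran_q, egger_regression, i2gx, ivw, leave_one_out,
                       mode_estimator, run_uvmr_suite, simulate_study,
                       wald_ratio, weighted_median)
from conftest import make_hset


class TestWaldRatio:
    def test_arithmetic(self):
        r = wald_ratio(0.5, 0.02, 0.25, 0.1)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_zero_outcome_gives_zero(self):
        assert wald_ratio(0.5, 0.02, 0.0, 0.1).estimate == 0.0

    def test_zero_exposure_errors(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.02, 0.25, 0.1)


class TestIVW:
    def test_two_variant_closed_form(self):
        h = make_hset([1, 1], [0.01, 0.01], [0.4, 0.6], [1, 1])
        r = ivw(h)
        assert r.estimate == pytest.approx(0.5)
        # Q = 0.02 < k-1, so the random-effects scale floors at 1
        assert r.se == pytest.approx(math.sqrt(0.5), rel=1e-12)

    def test_null_outcome_and_exact_proportionality(self):
        h0 = make_hset([0.3, 0.5, 0.7], [0.01] * 3, [0, 0, 0], [0.1] * 3)
        assert ivw(h0).estimate == 0.0
        bx = np.array([0.3, 0.5, 0.7])
        h1 = make_hset(bx, [0.01] * 3, 0.42 * bx, [0.1] * 3)
        r = ivw(h1)
        assert r.estimate == pytest.approx(0.42, rel=1e-12)
        assert cochran_q(h1, r.estimate).q == pytest.approx(0.0, abs=1e-20)

    def test_single_variant_delegates_to_wald(self):
        h = make_hset([0.5], [0.02], [0.25], [0.1])
        r = ivw(h)
        assert r.method == "wald"
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_weighted_least_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 30)
        bx = rng.uniform(0.02, 0.2, k)
        by = rng.normal(0.3 * bx, 0.05)
        so = rng.uniform(0.01, 0.1, k)
        h = make_hset(bx, np.full(k, 0.01), by, so)
        fit = sm.WLS(by, bx[:, None], weights=1.0 / so**2).fit()
        r = ivw(h, random_effects=False)
        assert r.estimate == pytest.approx(fit.params[0], rel=1e-10)

    def test_degenerate_instruments_error(self):
        h = make_hset([0.0, 0.0], [0.01, 0.01], [0.1, 0.2], [0.1, 0.1])
        with pytest.raises(EstimationError):
            ivw(h)

    def test_permutation_invariance_and_rescaling_equivariance(self, rng):
        k = 12
        bx = rng.uniform(0.02, 0.2, k)
        by = rng.normal(0.3 * bx, 0.05)
        sx, so = np.full(k, 0.01), rng.uniform(0.01, 0.1, k)
        h = make_hset(bx, sx, by, so)
        perm = rng.permutation(k)
        hp = make_hset(bx[perm], sx[perm], by[perm], so[perm])
        assert ivw(hp).estimate == pytest.approx(ivw(h).estimate, rel=1e-12)
        c = 3.7
        hs = make_hset(c * bx, c * sx, by, so)
        for fn in (lambda x: ivw(x).estimate,
                   lambda x: egger_regression(x)[0].estimate,
                   lambda x: weighted_median(x, n_boot=10, seed=0).estimate):
            assert fn(hs) == pytest.approx(fn(h) / c, rel=1e-9)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.1 + 0.3 * bx
        h = make_hset(bx, [0.01] * 3, by, [1.0] * 3)
        slope, intercept, het = egger_regression(h)
        assert slope.estimate == pytest.approx(0.3, rel=1e-10)
        assert intercept.estimate == pytest.approx(0.1, rel=1e-10)
        assert het.q == pytest.approx(0.0, abs=1e-18)

    def test_matches_wls_oracle(self, rng):
        k = 25
        bx = rng.uniform(0.05, 0.3, k)
        by = rng.normal(0.02 + 0.4 * bx, 0.05)
        so = rng.uniform(0.02, 0.08, k)
        h = make_hset(bx, np.full(k, 0.01), by, so)
        slope, intercept, _ = egger_regression(h, random_effects=False)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / so**2).fit()
        assert intercept.estimate == pytest.approx(fit.params[0], rel=1e-10)
        assert slope.estimate == pytest.approx(fit.params[1], rel=1e-10)

    def test_balanced_pleiotropy_mean_intercept_near_zero(self):
        rng = np.random.default_rng(11)
        reps, k = 400, 30
        intercepts = np.empty(reps)
        for i in range(reps):
            bx = rng.uniform(0.05, 0.2, k)
            alpha = rng.normal(0.0, 0.02, k)
            so = np.full(k, 0.01)
            by = 0.35 * bx + alpha + rng.normal(0, so)
            _, intercept, _ = egger_regression(make_hset(bx, np.full(k, 1e-4), by, so))
            intercepts[i] = intercept.estimate
        mc_se = intercepts.std(ddof=1) / math.sqrt(reps)
        assert abs(intercepts.mean()) < 3 * mc_se

    def test_directional_pleiotropy_recovered_by_intercept(self):
        rng = np.random.default_rng(12)
        k = 500
        bx = rng.uniform(0.05, 0.3, k)
        so = np.full(k, 0.005)
        by = 0.05 + 0.35 * bx + rng.normal(0, so)
        _, intercept, _ = egger_regression(make_hset(bx, np.full(k, 1e-5), by, so))
        assert intercept.estimate == pytest.approx(0.05, abs=0.002)

    def test_rank_deficient_design_errors(self):
        h = make_hset([0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.2, 0.3], [0.1] * 3)
        with pytest.raises(EstimationError):
            egger_regression(h)


class TestI2GX:
    def test_formula_and_truncation(self):
        # construct an 11-variant set whose Q_GX is exactly 100
        k = 11
        bx = np.zeros(k)
        bx[0] = 10.0 / math.sqrt(1 - 1 / k)  # Q_GX = bx0^2 * (1 - 1/k) = 100
        se = np.ones(k)
        h = make_hset(bx, se, np.zeros(k), np.ones(k))
        assert i2gx(h) == pytest.approx((100 - 10) / 100, rel=1e-9)
        # all equal exposure betas: Q_GX = 0 <= k-1, truncated to 0
        h0 = make_hset([0.1] * 5, [0.01] * 5, [0.0] * 5, [1.0] * 5)
        assert i2gx(h0) == 0.0


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_hset(bx, [0.01] * 3, 0.4 * bx, [0.1] * 3)
        assert weighted_median(h, n_boot=10, seed=0).estimate == pytest.approx(0.4)

    def test_hand_interpolation_equal_weights(self):
        bx = np.ones(3)
        by = np.array([1.0, 2.0, 3.0])
        h = make_hset(bx, [0.01] * 3, by, [1.0] * 3)
        assert weighted_median(h, n_boot=10, seed=0).estimate == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_cumulative_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 8))
        bx = rng.uniform(0.05, 0.3, k)
        by = rng.normal(0.3 * bx, 0.1)
        so = rng.uniform(0.02, 0.2, k)
        h = make_hset(bx, np.full(k, 0.01), by, so)
        got = weighted_median(h, n_boot=10, seed=0).estimate
        theta = by / bx
        w = (bx / so) ** 2
        assert got == pytest.approx(_weighted_median_oracle(theta, w), rel=1e-12)

    def test_robust_to_half_invalid_instruments(self):
        rng = np.random.default_rng(21)
        k = 100
        bx = rng.uniform(0.1, 0.3, k)
        so = np.full(k, 0.002)
        by = 0.3 * bx + rng.normal(0, so)
        by[: k // 2 - 5] += 0.08  # just under half the variants pleiotropic
        h = make_hset(bx, np.full(k, 1e-4), by, so)
        est = weighted_median(h, n_boot=10, seed=0).estimate
        assert est == pytest.approx(0.3, abs=0.02)


def _weighted_median_oracle(theta, w):
    pairs = sorted(zip(theta, w))
    total = sum(wi for _, wi in pairs)
    s = 0.0
    ps, ths = [], []
    for th, wi in pairs:
        ps.append((s + wi / 2) / total)
        s += wi
        ths.append(th)
    if ps[0] >= 0.5:
        return ths[0]
    if ps[-1] <= 0.5:
        return ths[-1]
    for j in range(1, len(ps)):
        if ps[j] >= 0.5:
            frac = (0.5 - ps[j - 1]) / (ps[j] - ps[j - 1])
            return ths[j - 1] + frac * (ths[j] - ths[j - 1])


class TestModeEstimator:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_hset(bx, [0.01] * 3, 0.25 * bx, [0.1] * 3)
        for weighted in (False, True):
            r = mode_estimator(h, weighted=weighted, n_boot=10, seed=0)
            assert r.estimate == pytest.approx(0.25)

    def test_majority_cluster_wins(self):
        theta = np.array([0.3, 0.3, 0.3, 0.3, 2.0])
        bx = np.ones(5)
        h = make_hset(bx, [0.01] * 5, theta, [0.1] * 5)
        r = mode_estimator(h, weighted=False, phi=1.0, n_boot=10, seed=0)
        grid_step = _grid_step(theta, phi=1.0)
        assert abs(r.estimate - 0.3) <= grid_step + 1e-12

    def test_weighted_mode_downweights_outlier(self):
        theta = np.array([0.3, 0.3, 0.3, 0.3, 2.0])
        bx = np.ones(5)
        so = np.array([0.1, 0.1, 0.1, 0.1, 10.0])  # outlier nearly weightless
        h = make_hset(bx, [0.01] * 5, theta, so)
        r = mode_estimator(h, weighted=True, phi=1.0, n_boot=10, seed=0)
        grid_step = _grid_step(theta, phi=1.0)
        assert abs(r.estimate - 0.3) <= grid_step + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_density_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = 9
        bx = rng.uniform(0.1, 0.3, k)
        by = rng.normal(0.3 * bx, 0.05)
        so = rng.uniform(0.05, 0.15, k)
        h = make_hset(bx, np.full(k, 0.01), by, so)
        got = mode_estimator(h, weighted=True, n_boot=10, seed=0).estimate
        theta = by / bx
        w = (bx / so) ** 2
        assert got == pytest.approx(_mode_oracle(theta, w, 1.0, 512), abs=1e-12)


def _grid_step(theta, phi):
    sd = np.std(theta, ddof=1)
    iqr = np.subtract(*np.percentile(theta, [75, 25]))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    hband = phi * 0.9 * s * len(theta) ** (-0.2)
    return (theta.max() - theta.min() + 6 * hband) / 511


def _mode_oracle(theta, w, phi, n_grid):
    """Loop-based kernel density argmax on the documented grid."""
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    s = min(sd, iqr / 1.349) if iqr > 0 else sd
    hband = phi * 0.9 * s * len(theta) ** (-0.2)
    lo, hi = min(theta) - 3 * hband, max(theta) + 3 * hband
    wn = [wi / sum(w) for wi in w]
    best_x, best_d = lo, -1.0
    for g in range(n_grid):
        x = lo + (hi - lo) * g / (n_grid - 1)
        d = sum(wi * math.exp(-0.5 * ((x - th) / hband) ** 2)
                for th, wi in zip(theta, wn))
        if d > best_d:
            best_x, best_d = x, d
    return best_x


class TestCochranQ:
    def test_zero_when_ratios_equal_estimate(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_hset(bx, [0.01] * 3, 0.5 * bx, [0.1] * 3)
        het = cochran_q(h, 0.5)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.pval == pytest.approx(1.0)

    def test_two_variant_hand_value(self):
        h = make_hset([1.0, 1.0], [0.01] * 2, [0.4, 0.6], [1.0, 1.0])
        het = cochran_q(h, 0.5)
        assert het.q == pytest.approx(0.02, rel=1e-12)
        assert het.df == 1

    def test_doubling_se_quarters_q(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.3, 6)
        by = rng.normal(0.3 * bx, 0.1)
        so = rng.uniform(0.05, 0.1, 6)
        q1 = cochran_q(make_hset(bx, [0.01] * 6, by, so), 0.3).q
        q2 = cochran_q(make_hset(bx, [0.01] * 6, by, 2 * so), 0.3).q
        assert q2 == pytest.approx(q1 / 4, rel=1e-12)


class TestLeaveOneOut:
    def test_homogeneous_set_stable_and_cardinality(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_hset(bx, [0.01] * 3, 0.5 * bx, [0.1] * 3)
        loo = leave_one_out(h)
        assert len(loo) == 3
        for _, r in loo:
            assert r.estimate == pytest.approx(0.5, rel=1e-10)

    def test_outlier_identified(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.3, 10)
        so = np.full(10, 0.005)
        by = 0.3 * bx + rng.normal(0, so)
        by[7] += 0.5  # gross outlier
        h = make_hset(bx, np.full(10, 0.001), by, so)
        full = ivw(h).estimate
        loo = leave_one_out(h)
        deltas = {vid: abs(r.estimate - full) for vid, r in loo}
        assert max(deltas, key=deltas.get) == "v7"


class TestRunUVMRSuite:
    def test_effect_recovery_through_full_pipeline(self, default_study):
        trait, _, outcome, ld, truth = default_study
        suite = run_uvmr_suite(trait, outcome, ld, MRConfig(seed=1, n_boot=50))
        assert suite.eligible
        r = suite.results["ivw"]
        assert r.estimate == pytest.approx(truth.implied_total, abs=5 * r.se)
        table = suite.table()
        assert set(table["method"]) == {"ivw", "egger-slope", "weighted-median",
                                        "simple-mode", "weighted-mode"}
        assert (table["ci_low"] <= table["estimate"]).all()
        assert (table["estimate"] <= table["ci_high"]).all()

    def test_nine_variant_instrument_ineligible(self):
        trait, _, outcome, ld, _ = simulate_study(
            SimulationConfig(n_snps_trait=9, n_snps_mediator=5, seed=3))
        suite = run_uvmr_suite(trait, outcome, ld, MRConfig())
        assert not suite.eligible
        assert suite.results is None
        assert suite.table().empty
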