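"""Growth-curve metrics, utilization features, exudate screen, LASSO regression."""

import numpy as np
import pandas as pd
import pytest

import phycosplit as ps
from phycosplit.traits import _fit_lasso, lasso_lambda_max


def curve(times, values, label=""):
    return ps.GrowthCurve(np.asarray(times, float), np.asarray(values, float), label)


class TestAuc:
    def test_constant_curve(self):
        c = curve([0, 2, 10], [3.0, 3.0, 3.0])
        assert ps.auc(c) == pytest.approx(30.0)

    def test_zero_curve(self):
        assert ps.auc(curve([0, 1, 2], [0, 0, 0])) == 0.0

    def test_exact_on_piecewise_linear(self):
        t = np.array([0.0, 1.0, 3.0])
        v = np.array([0.0, 2.0, 0.0])
        assert ps.auc(curve(t, v)) == pytest.approx(3.0)  # two triangles
        # refining the grid of a linear curve leaves the integral unchanged
        tf = np.linspace(0, 3, 301)
        vf = np.interp(tf, t, v)
        assert ps.auc(curve(tf, vf)) == pytest.approx(3.0)

    def test_unordered_times_rejected(self):
        with pytest.raises(ValueError):
            curve([0, 2, 1], [1, 1, 1])


class TestAucRatio:
    def test_identical_sets_ratio_one(self):
        reps = [curve([0, 1, 2], [1, 2, 3]) for _ in range(3)]
        ratio, sd = ps.auc_ratio(reps, reps)
        assert ratio == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_halved_co_culture(self):
        mono = [curve([0, 1, 2], [2, 4, 6]) for _ in range(2)]
        co = [curve([0, 1, 2], [1, 2, 3]) for _ in range(2)]
        ratio, _ = ps.auc_ratio(mono, co)
        assert ratio == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        mono = [curve([0, 1, 2], rng.random(3) + 1) for _ in range(3)]
        co = [curve([0, 1, 2], rng.random(3) + 1) for _ in range(3)]
        r1, s1 = ps.auc_ratio(mono, co)
        scaled = lambda cs: [curve(c.times, c.values * 7.3) for c in cs]
        r2, s2 = ps.auc_ratio(scaled(mono), scaled(co))
        assert r1 == pytest.approx(r2)
        assert s1 == pytest.approx(s2)

    def test_needs_replicates(self):
        c = [curve([0, 1], [1, 1])]
        with pytest.raises(ValueError):
            ps.auc_ratio(c, c * 2)


class TestGrowthFeatures:
    def test_exponential_rate_recovered(self):
        t = np.linspace(0, 10, 60)
        r = 0.35
        c = curve(t, 0.01 * np.exp(r * t))
        feats = ps.growth_features(c, offset=1e-6)
        assert feats["max_growth_rate"] == pytest.approx(r, rel=0.05)
        assert feats["grows"]

    def test_flat_below_floor_does_not_grow(self):
        c = curve(np.linspace(0, 10, 20), np.full(20, 0.01))
        feats = ps.growth_features(c)
        assert not feats["grows"]
        assert feats["max_od"] < 0.05

    def test_logistic_rate_matches_numerical_derivative(self):
        mono, _ = ps.simulate_growth_curves(n_points=80, noise_sd=0.0, capacity=1.0,
                                            n0=1e-3, rate=0.3, lag=5.0)
        feats = ps.growth_features(mono, offset=1e-8)
        log_v = np.log(mono.values + 1e-8)
        numeric = np.max(np.gradient(log_v, mono.times))
        assert feats["max_growth_rate"] == pytest.approx(numeric, rel=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ps.growth_features(curve([0, 1, 2], [1, 1, 1]))


class TestCapacityCompare:
    def test_identical_sets_not_significant(self):
        vals = np.array([2e7, 3e7, 2.5e7])
        rep = ps.capacity_compare(vals, vals)
        assert not rep["inconclusive"]
        assert not rep["significant"]

    def test_all_censored_inconclusive(self):
        low = np.array([1e3, 5e3])
        rep = ps.capacity_compare(low, low / 2)
        assert rep["inconclusive"]

    def test_fully_separated_statistic_one(self):
        with_a = np.array([1e8, 1.2e8, 0.9e8])
        without = with_a / 10
        rep = ps.capacity_compare(with_a, without)
        assert rep["statistic"] == 1.0
        assert rep["direction"] == "higher_with_algae"


class TestPositiveSlopeScreen:
    def test_constant_excluded_increasing_included(self):
        times = [0.0, 3.0, 6.0, 9.0]
        tbl = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0], [3.0, 2.0, 1.0, 0.0]],
            index=["flat", "up", "down"],
            columns=times,
        )
        base = pd.Series(0.0, index=tbl.index)
        out = ps.positive_slope_screen(tbl, base)
        assert not out.loc["flat", "secreted"]
        assert out.loc["up", "secreted"]
        assert not out.loc["down", "secreted"]

    def test_slope_matches_normal_equations(self):
        times = np.array([0.0, 2.0, 5.0, 7.0])
        y = np.array([0.1, 0.9, 2.2, 3.4])
        tbl = pd.DataFrame([y], index=["c"], columns=times)
        out = ps.positive_slope_screen(tbl, pd.Series(0.0, index=["c"]))
        tc = times - times.mean()
        expected = float(tc @ (y - y.mean()) / (tc @ tc))
        assert out.loc["c", "slope"] == pytest.approx(expected, abs=1e-12)

    def test_needs_three_timepoints(self):
        tbl = pd.DataFrame([[1.0, 2.0]], index=["c"], columns=[0.0, 1.0])
        with pytest.raises(ValueError):
            ps.positive_slope_screen(tbl, pd.Series(0.0, index=["c"]))


class TestLasso:
    def test_constant_response_degenerate(self, truth):
        g = truth.utilization
        r = pd.Series(0.5, index=g.isolates)
        fit = ps.lasso_trait_regression(g, r, n_repeats=2, n_shuffles=1, seed=0)
        assert fit.degenerate
        assert (fit.beta == 0).all()

    def test_all_zero_above_dual_norm_bound(self, truth):
        g, r = ps.simulate_trait_data(truth, seed=4)
        lam = lasso_lambda_max(g.g, r)
        X, y = g.g.to_numpy(float), r.to_numpy()
        assert np.allclose(_fit_lasso(X, y, lam * 1.0001).coef_, 0.0)
        assert np.any(_fit_lasso(X, y, lam * 0.9).coef_ != 0)

    def test_coefficient_path_monotone_l1(self, truth):
        g, r = ps.simulate_trait_data(truth, seed=4)
        X, y = g.g.to_numpy(float), r.to_numpy()
        lam_max = lasso_lambda_max(g.g, r)
        grid = np.geomspace(lam_max, lam_max * 1e-3, 15)
        norms = [np.abs(_fit_lasso(X, y, lam).coef_).sum() for lam in grid]
        for smaller_lam_norm, larger_lam_norm in zip(norms[1:], norms[:-1]):
            assert smaller_lam_norm >= larger_lam_norm - 1e-10

    def test_noiseless_support_recovery(self, truth):
        g, r = ps.simulate_trait_data(truth, noise_sd=0.0, seed=5)
        fit = ps.lasso_trait_regression(
            g, r, n_repeats=10, n_shuffles=2, shuffle_repeats=2, n_boot=500, seed=6
        )
        support = set(fit.beta.index[fit.beta.abs() > 1e-3])
        planted = set(truth.beta_true.index[truth.beta_true != 0])
        assert support == planted
        # coefficients match the OLS oracle on the planted support
        X = np.column_stack([np.ones(len(r)), g.g.to_numpy(float)])
        coef, *_ = np.linalg.lstsq(X, r.to_numpy(), rcond=None)
        ols = pd.Series(coef[1:], index=fit.beta.index)
        assert np.allclose(fit.beta[sorted(planted)], ols[sorted(planted)], atol=5e-3)
        assert fit.boot_p < 0.01

    def test_heldout_r2_band_on_planted_signal(self):
        """At study-scale designs the planted trait signal yields weak-but-real
        held-out R^2 (median-of-medians within 0.25-0.5) above the shuffled null."""
        meds = []
        for seed in range(1, 9):
            d = ps.DesignSpec(seed=seed)
            t = ps.make_ground_truth(d)
            g, r = ps.simulate_trait_data(t, seed=seed + 50)
            fit = ps.lasso_trait_regression(
                g, r, n_repeats=20, n_shuffles=4, shuffle_repeats=4,
                n_boot=300, seed=seed,
            )
            meds.append(float(np.median(fit.r2_real)))
            assert np.median(fit.r2_real) > np.median(fit.r2_shuffled)
        assert 0.25 <= float(np.median(meds)) <= 0.5
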