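"""Dispersion methods (moving window, residuals, BIC) and k selection."""

import math

import numpy as np
import pytest

from clusterdose.association import (
    DispersionResult,
    bic_bootstrap,
    bic_score,
    lq_residual_dispersion,
    moving_window,
    moving_window_variable,
    select_preferred_ip,
)
from clusterdose.lq import fit_lq, fit_lq_arrays
from conftest import lq_dataset, make_cluster_dose_points


def brute_force_moving_window(survivals, n):
    """Oracle: enumerate every window; left-to-right accumulation, as the
    window SD contract specifies."""
    sigmas = []
    N = len(survivals)
    for start in range(N - n + 1):
        window = survivals[start : start + n]
        m = 0.0
        for v in window:
            m += v
        m /= n
        ss = 0.0
        for v in window:
            ss += (v - m) * (v - m)
        sigmas.append(math.sqrt(ss / n))
    mean = 0.0
    for v in sigmas:
        mean += v
    mean /= len(sigmas)
    ss = 0.0
    for v in sigmas:
        ss += (v - mean) * (v - mean)
    se = math.sqrt(ss / len(sigmas)) / math.sqrt(len(sigmas))
    return sigmas, mean, se


def sorted_points(g, s):
    pts = make_cluster_dose_points(g, s)
    return sorted(pts, key=lambda p: p.g)


class TestMovingWindow:
    def test_equal_survivals_zero_dispersion(self):
        pts = sorted_points(np.linspace(1, 10, 20), np.full(20, 0.5))
        res = moving_window(pts)
        assert res.statistic == 0.0
        assert res.se == 0.0

    def test_single_window_is_population_sd(self):
        s = np.array([0.9, 0.5, 0.7, 0.3])
        pts = sorted_points(np.arange(1.0, 5.0), s)
        res = moving_window(pts, window_fraction=1.0, min_window=4)
        assert res.n_units == 1
        assert res.statistic == pytest.approx(np.std(s), rel=1e-12)
        assert res.se == 0.0

    def test_matches_brute_force_bit_exact(self):
        rng = np.random.default_rng(17)
        g = np.sort(rng.uniform(0, 50, size=200))
        s = np.exp(-0.1 * g) * np.exp(rng.normal(0, 0.2, size=200))
        pts = sorted_points(g, s)
        res = moving_window(pts, window_fraction=0.02)  # n = 4
        _, mean, se = brute_force_moving_window([p.survival for p in pts], 4)
        assert res.statistic == mean  # bit-exact
        assert res.se == se

    def test_window_size_rounding_half_up(self):
        pts = sorted_points(np.arange(1.0, 351.0), np.full(350, 0.5))
        # 0.01 * 350 = 3.5 -> rounds half-up to 4
        res = moving_window(pts, window_fraction=0.01)
        assert res.settings["window_size"] == 4

    def test_minimum_window_enforced(self):
        pts = sorted_points(np.arange(1.0, 41.0), np.full(40, 0.5))
        res = moving_window(pts, window_fraction=0.01)  # 0.4 -> min 3
        assert res.settings["window_size"] == 3
        assert res.n_units == 38

    def test_unsorted_input_rejected(self):
        pts = make_cluster_dose_points([3.0, 1.0, 2.0], [0.5, 0.6, 0.7])
        with pytest.raises(ValueError, match="sorted"):
            moving_window(pts)

    def test_too_few_points_rejected(self):
        pts = sorted_points([1.0, 2.0], [0.5, 0.6])
        with pytest.raises(ValueError, match="at least 3"):
            moving_window(pts)


class TestMovingWindowVariable:
    def test_sparse_dataset_undefined(self):
        # spacing far beyond 5% of g -> every window a singleton
        g = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        pts = sorted_points(g, np.full(5, 0.5))
        with pytest.raises(ValueError, match="fewer than 2"):
            moving_window_variable(pts)

    def test_equal_survivals_zero(self):
        g = np.repeat(np.linspace(1, 5, 10), 3)  # dense: triplicate doses
        pts = sorted_points(g, np.full(30, 0.42))
        res = moving_window_variable(pts)
        assert res.statistic == 0.0
        assert res.settings["n_skipped"] == 0

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(23)
        g = np.sort(rng.uniform(10, 12, size=60))  # dense band
        s = rng.uniform(0.2, 0.8, size=60)
        pts = sorted_points(g, s)
        res = moving_window_variable(pts, g_fraction=0.05)
        # independent enumeration
        sigmas = []
        for i in range(60):
            sel = [
                pts[j].survival
                for j in range(60)
                if abs(pts[j].g - pts[i].g) <= 0.05 * pts[i].g
            ]
            if len(sel) >= 2:
                m = sum(sel) / len(sel)
                sigmas.append(math.sqrt(sum((v - m) ** 2 for v in sel) / len(sel)))
        assert res.n_units == len(sigmas)
        assert res.statistic == pytest.approx(float(np.mean(sigmas)), rel=1e-12)


class TestLQResidualDispersion:
    def test_zero_on_fitted_curve(self):
        g = np.linspace(1, 10, 12)
        s = np.exp(-0.2 * g - 0.01 * g**2)
        pts = sorted_points(g, s)
        res = lq_residual_dispersion(pts, fit_lq(pts))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_relative_residual_arithmetic(self):
        # r = |S - Ŝ|/Ŝ: points (1.0 vs 0.8) and (0.5 vs 0.5) -> mean 0.125
        from clusterdose.lq import LQFitResult

        fit = LQFitResult(
            alpha=math.log(1 / 0.8), beta=0.0, covariance=np.zeros((2, 2)),
            chi2=0.0, n_points=2,
        )
        pts = make_cluster_dose_points([1.0, 2.0], [1.0, 0.8**2])
        # Ŝ(1) = 0.8, Ŝ(2) = 0.64 -> r = (0.25, 0)
        res = lq_residual_dispersion(pts, fit)
        assert res.statistic == pytest.approx(0.125, rel=1e-12)
        assert res.se == pytest.approx(np.std([0.25, 0.0]) / math.sqrt(2), rel=1e-12)


class TestBIC:
    def test_gaussian_formula_wiring(self):
        rng = np.random.default_rng(31)
        g, s = lq_dataset(rng, n=20)
        pts = sorted_points(g, s)
        res = bic_score(pts, model="lq", convention="gaussian")
        # recompute -2 log L independently from the same weighted fit
        fit = fit_lq_arrays(g[np.argsort(g)], s[np.argsort(g)])
        resid = np.log([p.survival for p in pts]) - fit.predict_log_survival(
            np.array([p.g for p in pts])
        )
        ssr = float(np.sum(resid**2))
        sigma = float(np.std(resid))
        N = 20
        expected_llh = N * math.log(2 * math.pi) + 2 * N * math.log(sigma) + ssr / sigma**2
        assert res.llh == pytest.approx(expected_llh, rel=1e-10)
        assert res.bic == pytest.approx(expected_llh + 2 * math.log(N), rel=1e-10)

    def test_bic_ordering_equals_ssr_ordering_at_fixed_n(self):
        """Across candidate k the model class and N are fixed, so BIC must
        rank alternatives exactly as the residual sum does."""
        rng = np.random.default_rng(8)
        g, s = lq_dataset(rng, n=30)
        pts_good = sorted_points(g, s)
        noisy = s * np.exp(rng.normal(0, 0.4, size=30))
        pts_bad = sorted_points(g, noisy)
        good = bic_score(pts_good, convention="gaussian")
        bad = bic_score(pts_bad, convention="gaussian")
        assert good.bic < bad.bic

    def test_gaussian_monotone_in_residual_spread_legacy_is_not(self):
        """The Gaussian BIC grows with the residual spread (worse fit, higher
        score), which is what makes the k-selection argmin meaningful.  The
        literal legacy surrogate −N ln σ + SSR/σ² moves the opposite way once
        σ is estimated from the residuals (SSR/σ² ≈ N, so −N ln σ dominates);
        it is kept only for traceability and must not drive selection."""
        rng = np.random.default_rng(12)
        noise_levels = [0.02, 0.1, 0.4]
        bics_g, bics_p = [], []
        for sd in noise_levels:
            g, s = lq_dataset(rng, n=200, noise_sd=sd)
            pts = sorted_points(g, s)
            bics_g.append(bic_score(pts, convention="gaussian").bic)
            bics_p.append(bic_score(pts, convention="paper").bic)
        assert bics_g == sorted(bics_g)
        assert bics_p == sorted(bics_p, reverse=True)

    def test_lq_beats_linear_on_quadratic_data(self):
        rng = np.random.default_rng(2)
        g, s = lq_dataset(rng, alpha=0.3, beta=0.02, noise_sd=0.1, n=40)
        pts = sorted_points(g, s)
        assert bic_score(pts, "lq").bic < bic_score(pts, "linear").bic

    def test_insufficient_points(self):
        pts = sorted_points([1.0, 2.0], [0.5, 0.3])
        with pytest.raises(ValueError, match="at least 3"):
            bic_score(pts, "lq")


class TestBICBootstrap:
    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(14)
        g, s = lq_dataset(rng, n=30)
        pts = sorted_points(g, s)
        r1 = bic_bootstrap(pts, seed=99)
        r2 = bic_bootstrap(pts, seed=99)
        assert r1.statistic == r2.statistic
        assert r1.se == r2.se

    def test_zero_noise_se_from_penalty_only(self):
        g = np.linspace(1, 10, 30)
        pts = sorted_points(g, np.exp(-0.2 * g - 0.01 * g**2))
        res = bic_bootstrap(pts, seed=5)
        # all subsamples have the same size -> identical penalty; residuals
        # are at round-off level, so the SE is tiny relative to the statistic
        assert res.se < 0.01 * abs(res.statistic)

    def test_subsample_too_small(self):
        pts = sorted_points([1.0, 2.0, 3.0], [0.5, 0.4, 0.3])
        with pytest.raises(ValueError, match="subsample"):
            bic_bootstrap(pts, subsample_fraction=0.5)


class TestSelectPreferredIp:
    def mk(self, stat, se=1e-6, method="moving_window", settings=None):
        return DispersionResult(
            method=method, statistic=stat, se=se, n_units=10,
            settings=settings or {"window_fraction": 0.01},
        )

    def test_argmin(self):
        results = {4: self.mk(5.0), 5: self.mk(3.0), 6: self.mk(4.0)}
        sel = select_preferred_ip(results)
        assert sel.selected_k == 5
        assert sel.within_se == (5,)

    def test_indistinguishable_ks_flagged(self):
        results = {4: self.mk(3.05, se=0.1), 5: self.mk(3.0, se=0.1), 6: self.mk(9.0)}
        sel = select_preferred_ip(results)
        assert sel.selected_k == 5
        assert set(sel.within_se) == {4, 5}

    def test_mixed_settings_rejected(self):
        results = {
            4: self.mk(1.0, settings={"window_fraction": 0.01}),
            5: self.mk(2.0, settings={"window_fraction": 0.05}),
        }
        with pytest.raises(ValueError, match="settings"):
            select_preferred_ip(results)

    def test_mixed_methods_rejected(self):
        results = {4: self.mk(1.0), 5: self.mk(2.0, method="bic")}
        with pytest.raises(ValueError, match="methods"):
            select_preferred_ip(results)

    def test_requires_two_ks(self):
        with pytest.raises(ValueError, match="at least 2"):
            select_preferred_ip({5: self.mk(1.0)})
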