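"""Drift estimation, autocorrelation and portmanteau test diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import least_squares
from statsmodels.stats.diagnostic import acorr_ljungbox

from nodewalk import (
    NumericalError,
    acf,
    difference_series,
    estimate_drift,
    fit_random_walk,
    portmanteau_test,
    reconstruct_series,
)

finite_series = st.lists(
    st.floats(min_value=-10.0, max_value=10.0, allow_nan=False), min_size=3, max_size=60
).map(np.asarray)


class TestDifferencing:
    def test_examples(self):
        np.testing.assert_allclose(difference_series([1.0, 1.0, 1.0]), [0.0, 0.0])
        np.testing.assert_allclose(difference_series([1.0, 1.3, 1.1]), [0.3, -0.2])

    def test_too_short(self):
        with pytest.raises(NumericalError):
            difference_series([1.0])

    @settings(derandomize=True, deadline=None)
    @given(finite_series)
    def test_cumsum_inverts_differencing(self, H):
        d = difference_series(H)
        np.testing.assert_allclose(np.concatenate([[H[0]], H[0] + np.cumsum(d)]), H, atol=1e-12)


class TestEstimateDrift:
    def test_pure_drift_line(self):
        H = 1.0 + 0.02 * np.arange(60)
        fit = estimate_drift(difference_series(H), h0=H[0])
        assert fit.mu == pytest.approx(0.02, abs=1e-14)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-28)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-14)

    @settings(derandomize=True, deadline=None)
    @given(finite_series)
    def test_telescoping_and_centred_residuals(self, H):
        fit = estimate_drift(difference_series(H), h0=H[0])
        assert fit.mu == pytest.approx((H[-1] - H[0]) / (len(H) - 1), rel=1e-12, abs=1e-12)
        assert abs(fit.residuals.mean()) < 1e-12
        assert fit.sigma2 >= 0.0
        assert fit.n_diffs == len(H) - 1

    @settings(derandomize=True, deadline=None)
    @given(finite_series)
    def test_reconstruction_round_trip(self, H):
        fit = estimate_drift(difference_series(H), h0=H[0])
        np.testing.assert_allclose(
            reconstruct_series(fit.mu, fit.h0, fit.residuals), H, atol=1e-12
        )

    def test_unbiased_drift_recovery(self):
        # Monte-Carlo oracle: mean of mu-hat over many simulated walks
        rng = np.random.default_rng(42)
        mu, sigma, length, reps = 0.05, 0.06, 60, 3000
        mus = np.empty(reps)
        for r in range(reps):
            d = rng.normal(mu, sigma, length - 1)
            mus[r] = estimate_drift(d).mu
        mc_se = sigma / np.sqrt(length - 1) / np.sqrt(reps)
        assert abs(mus.mean() - mu) < 3 * mc_se

    def test_too_few_differences(self):
        with pytest.raises(NumericalError):
            estimate_drift([0.1])


class TestAcf:
    def test_lag_zero_is_one(self):
        assert acf(np.random.default_rng(0).normal(size=30), 5).rho[0] == 1.0

    def test_alternating_series_closed_form(self):
        x = np.array([1.0, -1.0] * 4)
        assert acf(x, 1).rho[1] == pytest.approx(-0.875)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=40)
        res = acf(x, 8)
        xc = x - x.mean()
        denom = (xc**2).sum()
        for k in range(9):
            num = sum(xc[t] * xc[t - k] for t in range(k, 40))
            assert res.rho[k] == pytest.approx(num / denom, abs=1e-12)
        assert np.all(np.abs(res.rho) <= 1.0 + 1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(NumericalError):
            acf(np.ones(20), 3)

    def test_series_too_short_for_lag(self):
        with pytest.raises(NumericalError):
            acf(np.arange(5.0), 5)


class TestPortmanteau:
    def test_zero_acf_series_gives_q_zero_p_one(self):
        # construct a series whose sample autocorrelations vanish at lags 1..4
        h, n = 4, 16
        rng = np.random.default_rng(3)
        tail = rng.normal(size=n - h)  # fixed; solve for the first h entries

        def autocovs(theta):
            x = np.concatenate([theta, tail])
            xc = x - x.mean()
            return [xc[k:] @ xc[:-k] for k in range(1, h + 1)]

        start = np.random.default_rng(0).normal(size=h)
        sol = least_squares(autocovs, start, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        x = np.concatenate([sol.x, tail])
        assert np.max(np.abs(autocovs(sol.x))) < 1e-10
        res = portmanteau_test(x, lags=h)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_statsmodels_ljung_box_and_box_pierce(self):
        x = np.random.default_rng(8).normal(size=20)
        sm = acorr_ljungbox(x, lags=5, boxpierce=True)
        lb = portmanteau_test(x, lags=5, variant="ljung-box")
        bp = portmanteau_test(x, lags=5, variant="box-pierce")
        assert lb.Q == pytest.approx(sm["lb_stat"].iloc[-1], abs=1e-6)
        assert lb.p == pytest.approx(sm["lb_pvalue"].iloc[-1], abs=1e-6)
        assert bp.Q == pytest.approx(sm["bp_stat"].iloc[-1], abs=1e-6)
        assert bp.p == pytest.approx(sm["bp_pvalue"].iloc[-1], abs=1e-6)

    def test_type_one_error_near_nominal(self):
        # calibration in the regime where the chi-square null is accurate
        # (long series, few lags); short series with many lags over-reject,
        # a known finite-sample property of the asymptotic reference
        rng = np.random.default_rng(17)
        reps, n, h, alpha = 1500, 300, 5, 0.05
        rej = sum(portmanteau_test(rng.normal(size=n), lags=h).p < alpha for _ in range(reps))
        rate = rej / reps
        band = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < band

    def test_power_against_ar1(self):
        rng = np.random.default_rng(23)
        reps, n, h, phi = 400, 80, 10, 0.8
        rej = 0
        for _ in range(reps):
            eps = rng.normal(size=n)
            x = np.empty(n)
            x[0] = eps[0] / np.sqrt(1 - phi**2)
            for t in range(1, n):
                x[t] = phi * x[t - 1] + eps[t]
            rej += portmanteau_test(x, lags=h).p < 0.05
        assert rej / reps > 0.8

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(NumericalError):
            portmanteau_test(np.zeros(30), lags=5)
        with pytest.raises(NumericalError):
            portmanteau_test(np.random.default_rng(0).normal(size=8), lags=10)


class TestReconstruct:
    def test_no_drift_no_noise_constant(self):
        np.testing.assert_allclose(reconstruct_series(0.0, 1.5, np.zeros(10)), 1.5)

    def test_pure_drift_line(self):
        H = reconstruct_series(0.02, 1.0, np.zeros(50))
        np.testing.assert_allclose(H, 1.0 + 0.02 * np.arange(51))

    def test_nonfinite_rejected(self):
        with pytest.raises(NumericalError):
            reconstruct_series(np.nan, 1.0, np.zeros(3))


class TestFitRandomWalk:
    def test_pure_drift_surfaces_zero_variance(self):
        H = 1.0 + 0.02 * np.arange(40)
        with pytest.raises(NumericalError):
            fit_random_walk(H, lags=5)

    def test_drift_recovery_from_model_truth(self):
        # series simulated from the drift model itself
        rng = np.random.default_rng(11)
        mu, sigma2, length = 0.02, 0.004, 80
        H = 1.0 + np.cumsum(np.r_[0.0, rng.normal(mu, np.sqrt(sigma2), length - 1)])
        fit = fit_random_walk(H, lags=10)
        assert abs(fit.drift.mu - mu) < 3 * np.sqrt(sigma2 / (length - 1))
        assert fit.portmanteau.df == 10

    def test_default_lag_rule(self):
        rng = np.random.default_rng(4)
        fit = fit_random_walk(1.0 + np.cumsum(rng.normal(0.02, 0.06, 30)), lags=None)
        assert fit.portmanteau.lags == min(10, 29 // 5)

    def test_too_short_series(self):
        with pytest.raises(NumericalError):
            fit_random_walk(np.array([1.0, 1.1, 1.2]), lags=10)
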