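"""Empirical autocorrelation estimators and the G1/G2 closed-form models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bayestics.correlation import (
    AutocorrCurve,
    ROISeries,
    Theta,
    _pair_ks,
    default_max_lag,
    empirical_autocorr_fluctuation,
    empirical_autocorr_uniform,
    inverse_g1_line,
    model_g1,
    model_g2,
)
from tests.conftest import A_TRUE, D_TRUE

LAGS = np.arange(1, 26)


def constant_series(value=3.0, t=40, size=9):
    return ROISeries(np.full((t, size, size), value))


class TestEmpiricalUniform:
    def test_constant_sequence_gives_square(self):
        curve = empirical_autocorr_uniform(constant_series(3.0), max_lag=10)
        np.testing.assert_allclose(curve.values, 9.0, rtol=1e-12)

    def test_matches_bruteforce_pooled_products(self, rng):
        """Oracle: naive loop re-implementation of the pooled pair average."""
        data = rng.normal(2.0, 1.0, size=(30, 7, 7))
        roi = ROISeries(data, t0=2)
        n_ref = 4
        curve = empirical_autocorr_uniform(roi, max_lag=12, n_ref=n_ref)
        for lag, value in zip(curve.lags, curve.values):
            ks = [k for k in range(n_ref) if k < (lag + 1) // 2]
            expected = np.mean(
                [np.mean(data[2 + k] * data[2 + lag - k]) for k in ks]
            )
            assert value == pytest.approx(expected, rel=1e-12)

    def test_noise_free_render_matches_model_g1(self, noise_free_roi):
        """Central oracle-equivalence: rendered spot curve equals the closed form."""
        max_lag = default_max_lag(noise_free_roi.n_frames)
        curve = empirical_autocorr_uniform(noise_free_roi, max_lag)
        model = model_g1(curve.lags, Theta(D_TRUE, A_TRUE), noise_free_roi.roi_dims)
        np.testing.assert_allclose(curve.values, model.values, rtol=0.02)

    def test_white_noise_curve_small_under_time_reversal(self, rng):
        sigma = 1.0
        data = rng.normal(0.0, sigma, size=(2000, 15, 15))
        bound = 5.0 * sigma**2 / np.sqrt(15 * 15)  # per-pair product noise scale
        for stack in (data, data[::-1]):
            curve = empirical_autocorr_uniform(ROISeries(stack), max_lag=20)
            pairs = np.minimum(10, (curve.lags + 1) // 2)
            assert np.all(np.abs(curve.values) < bound / np.sqrt(pairs))

    def test_lag_grid_validation(self):
        roi = constant_series(t=20)
        with pytest.raises(ValueError):
            empirical_autocorr_uniform(roi, max_lag=20)
        with pytest.raises(ValueError):
            empirical_autocorr_uniform(roi, max_lag=5, tau_min=-1)

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 10.0))
    def test_quadratic_homogeneity(self, scale):
        data = np.random.default_rng(7).normal(1.0, 0.5, size=(25, 5, 5))
        base = empirical_autocorr_uniform(ROISeries(data), 8)
        scaled = empirical_autocorr_uniform(ROISeries(scale * data), 8)
        np.testing.assert_allclose(scaled.values, scale**2 * base.values, rtol=1e-9)


class TestEmpiricalFluctuation:
    def test_constant_sequence_gives_zero(self):
        curve = empirical_autocorr_fluctuation(constant_series(5.0), max_lag=8)
        np.testing.assert_allclose(curve.values, 0.0, atol=1e-12)

    def test_offset_invariance(self, rng):
        data = rng.normal(4.0, 1.0, size=(60, 9, 9))
        base = empirical_autocorr_fluctuation(ROISeries(data), 10)
        shifted = empirical_autocorr_fluctuation(ROISeries(data + 17.0), 10)
        np.testing.assert_allclose(shifted.values, base.values, rtol=1e-9, atol=1e-12)

    def test_white_noise_curve_vanishes(self, rng):
        # debiased estimator: noise floor sigma^2/tail removed, remainder is
        # Monte-Carlo noise of order sigma^2/sqrt(N*pairs)
        sigma = 1.0
        data = rng.normal(0.0, sigma, size=(2000, 15, 15))
        curve = empirical_autocorr_fluctuation(ROISeries(data), max_lag=20)
        pairs = np.minimum(10, (curve.lags + 1) // 2)
        bound = 5.0 * sigma**2 / np.sqrt(15 * 15 * pairs)
        assert np.all(np.abs(curve.values) < bound + 0.2 * sigma**2 / 20)

    def test_matches_model_g2_on_noise_free_render(self, noise_free_roi):
        # the wide tail-baseline products feel the ROI border, hence the
        # looser 5% agreement compared with the G1 oracle equivalence
        curve = empirical_autocorr_fluctuation(noise_free_roi, 25)
        model = model_g2(
            curve.lags, Theta(D_TRUE, A_TRUE), noise_free_roi.roi_dims,
            noise_free_roi.n_frames,
        )
        np.testing.assert_allclose(curve.values, model.values, rtol=0.05)


class TestModelG1:
    def test_inverse_is_affine_in_lag(self):
        lags = np.arange(1, 51)
        curve = model_g1(lags, Theta(D_TRUE, A_TRUE), (31, 31))
        inv = 1.0 / curve.values
        coef = np.polyfit(lags.astype(float), inv, 1)
        resid = inv - np.polyval(coef, lags.astype(float))
        r2 = 1.0 - np.sum(resid**2) / np.sum((inv - inv.mean()) ** 2)
        assert r2 >= 1.0 - 1e-6

    def test_roi_size_factor_scales_curve(self):
        theta = Theta(0.7, 1e5)
        small = model_g1(LAGS, theta, (15, 15))
        large = model_g1(LAGS, theta, (30, 15))  # doubled pixel count
        np.testing.assert_allclose(small.values, 2.0 * large.values, rtol=1e-12)

    def test_same_d_curves_proportional(self):
        c1 = model_g1(LAGS, Theta(0.4, 1e5), (31, 31)).values
        c2 = model_g1(LAGS, Theta(0.4, 3e5), (31, 31)).values
        np.testing.assert_allclose(c2 / c1, 3.0, rtol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(d=st.floats(0.01, 5.0), a=st.floats(1e2, 1e7))
    def test_strictly_decreasing(self, d, a):
        values = model_g1(LAGS, Theta(d, a), (31, 31)).values
        assert np.all(np.diff(values) < 0)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            Theta(-1.0, 1.0)
        with pytest.raises(ValueError):
            Theta(1.0, 0.0)


class TestModelG2:
    def test_approaches_g1_monotonically_in_t(self):
        theta = Theta(D_TRUE, A_TRUE)
        g1 = model_g1(LAGS, theta, (31, 31)).values
        deviations = []
        for T in (300, 600, 1200, 2400, 4800):
            g2 = model_g2(LAGS, theta, (31, 31), T).values
            deviations.append(np.max(np.abs(g2 / g1 - 1.0)))
        assert all(a > b for a, b in zip(deviations, deviations[1:]))
        assert deviations[-1] < 0.01

    def test_infinite_t_limit_is_g1(self):
        # correction terms decay like 1/T, so at astronomical T they vanish
        theta = Theta(0.8, 2e5)
        g1 = model_g1(LAGS, theta, (31, 31)).values
        g2 = model_g2(LAGS, theta, (31, 31), T=10**7).values
        np.testing.assert_allclose(g2, g1, rtol=1e-4)

    def test_roi_size_factor_scales_curve(self):
        theta = Theta(0.5, 1e5)
        small = model_g2(LAGS, theta, (15, 15), 300).values
        large = model_g2(LAGS, theta, (30, 15), 300).values
        np.testing.assert_allclose(small, 2.0 * large, rtol=1e-12)

    def test_t_validation(self):
        with pytest.raises(ValueError):
            model_g2(LAGS, Theta(0.5, 1e5), (31, 31), T=1)

    @settings(derandomize=True, max_examples=30)
    @given(d=st.floats(0.05, 3.0), a=st.floats(1e3, 1e7))
    def test_strictly_decreasing(self, d, a):
        values = model_g2(LAGS, Theta(d, a), (31, 31), 300).values
        assert np.all(np.diff(values) < 0)


class TestInverseG1Line:
    def test_matches_inverse_model_pointwise(self):
        theta = Theta(0.6, 2e5)
        slope, intercept = inverse_g1_line(theta, (31, 31))
        curve = model_g1(np.arange(1, 40), theta, (31, 31))
        np.testing.assert_allclose(
            slope * curve.lags + intercept, 1.0 / curve.values, rtol=1e-12
        )

    def test_slope_increasing_in_d(self):
        slopes = [inverse_g1_line(Theta(d, 1e5), (31, 31))[0] for d in (0.1, 0.3, 0.9, 2.7)]
        assert all(a < b for a, b in zip(slopes, slopes[1:]))

    def test_intercept_positive(self):
        _, intercept = inverse_g1_line(Theta(0.5, 1e5), (31, 31))
        assert intercept > 0


class TestCurveContainer:
    def test_csv_round_trip(self):
        curve = AutocorrCurve(
            np.arange(1, 6), np.array([5.0, 4.0, 3.5, 3.1, 2.9]),
            variant="uniform", meta={"T": 100},
        )
        restored = AutocorrCurve.from_csv(curve.to_csv())
        np.testing.assert_array_equal(restored.lags, curve.lags)
        np.testing.assert_allclose(restored.values, curve.values, rtol=0)
        assert restored.variant == "uniform"

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            AutocorrCurve(np.array([2, 1]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            AutocorrCurve(np.array([1, 2]), np.array([1.0, np.inf]))

    def test_pair_pooling_schedule(self):
        assert list(_pair_ks(1, 10)) == [0]
        assert list(_pair_ks(5, 10)) == [0, 1, 2]
        assert list(_pair_ks(25, 10)) == list(range(10))
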