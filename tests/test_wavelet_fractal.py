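"""Wavelet covariance scaling, the asymptotic constant, and both estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fractalconn import (
    MemoryParams,
    ShortMemoryCov,
    asymptotic_beta,
    estimate_memory_parameter,
    estimate_short_memory_cov,
    simulate_multivariate_fin,
    wavelet_correlation,
    wavelet_covariance,
    wavelet_decompose,
)
from fractalconn.wavelet_fractal import ScaleCovariances


class TestDecompose:
    def test_constant_series_has_vanishing_details(self):
        V = wavelet_decompose(np.full(256, 3.7), Q=4)
        for d in V.details:
            assert np.max(np.abs(d)) < 1e-10

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_energy_conservation(self, seed):
        x = np.random.default_rng(seed).standard_normal(256)
        V = wavelet_decompose(x, Q=5)
        energy = sum(float(d @ d) for d in V.details) + float(V.approx @ V.approx)
        assert energy == pytest.approx(float(x @ x), rel=1e-8)

    def test_decimated_coefficient_counts(self):
        V = wavelet_decompose(np.random.default_rng(0).standard_normal(256), Q=5)
        assert V.n_coeffs == (128, 64, 32, 16, 8)

    def test_white_noise_variance_flat_across_scales(self):
        slopes = []
        for s in range(50):
            x = np.random.default_rng(s).standard_normal(4096)
            V = wavelet_decompose(x)
            ups = wavelet_covariance(V, V)
            q = ups.scales()
            slopes.append(np.polyfit(q, np.log2(ups.upsilon), 1)[0])
        assert abs(np.mean(slopes)) < 0.1

    def test_too_deep_request_names_feasible_depth(self):
        with pytest.raises(ValueError, match="maximum is 6"):
            wavelet_decompose(np.zeros(64), Q=8)


class TestWaveletCovariance:
    def test_self_covariance_is_per_scale_variance(self, rng):
        x = rng.standard_normal(512)
        V = wavelet_decompose(x, Q=4)
        ups = wavelet_covariance(V, V)
        for q0, d in enumerate(V.details):
            assert ups.upsilon[q0] == pytest.approx(float(d @ d) / d.size)
            assert ups.upsilon[q0] >= 0

    def test_bilinearity_under_negation(self, rng):
        x = rng.standard_normal(512)
        Vx = wavelet_decompose(x, Q=4)
        Vy = wavelet_decompose(-x, Q=4)
        np.testing.assert_allclose(
            wavelet_covariance(Vx, Vy).upsilon,
            -wavelet_covariance(Vx, Vx).upsilon,
            rtol=1e-12,
        )

    def test_log_slope_matches_sum_of_exponents(self, bivariate_fin):
        ts, params, _ = bivariate_fin
        Vx = wavelet_decompose(ts.values[:, 0])
        Vy = wavelet_decompose(ts.values[:, 1])
        ups = wavelet_covariance(Vx, Vy)
        q = np.arange(2, ups.n_scales + 1)
        slope = np.polyfit(q, np.log2(ups.upsilon[q - 1]), 1)[0]
        assert slope == pytest.approx(params.a.sum(), abs=0.15)

    def test_variance_log_slope_is_twice_exponent(self):
        # asymptotic scaling: log2 ups_xx(q) grows at rate 2a
        slopes = []
        for s in range(6):
            ts = simulate_multivariate_fin(
                MemoryParams([0.3]), ShortMemoryCov([[1.0]]), 8192, seed=s
            )
            V = wavelet_decompose(ts.values[:, 0])
            ups = wavelet_covariance(V, V)
            q = np.arange(2, ups.n_scales + 1)
            slopes.append(np.polyfit(q, np.log2(ups.upsilon[q - 1]), 1)[0])
        assert np.mean(slopes) == pytest.approx(0.6, abs=0.1)


class TestWaveletCorrelation:
    def test_identical_channels_give_unit_correlation(self, rng):
        x = rng.standard_normal(512)
        V = wavelet_decompose(x, Q=4)
        ups = wavelet_covariance(V, V)
        np.testing.assert_allclose(wavelet_correlation(ups, ups, ups), 1.0)

    def test_independent_channels_near_zero(self, rng):
        x, y = rng.standard_normal((2, 8192))
        Vx, Vy = wavelet_decompose(x, Q=6), wavelet_decompose(y, Q=6)
        d = wavelet_correlation(
            wavelet_covariance(Vx, Vy),
            wavelet_covariance(Vx, Vx),
            wavelet_covariance(Vy, Vy),
        )
        assert np.nanmax(np.abs(d[:4])) < 0.15  # fine scales: many coefficients

    def test_bounded_in_unit_interval(self, bivariate_fin):
        ts, _, _ = bivariate_fin
        Vx = wavelet_decompose(ts.values[:, 0])
        Vy = wavelet_decompose(ts.values[:, 1])
        d = wavelet_correlation(
            wavelet_covariance(Vx, Vy),
            wavelet_covariance(Vx, Vx),
            wavelet_covariance(Vy, Vy),
        )
        assert np.all(np.abs(d[np.isfinite(d)]) <= 1.0)

    def test_coarse_scale_correlation_approaches_fractal_limit(self, bivariate_fin):
        ts, params, cov = bivariate_fin
        ax, ay = params.a
        Vx = wavelet_decompose(ts.values[:, 0])
        Vy = wavelet_decompose(ts.values[:, 1])
        d = wavelet_correlation(
            wavelet_covariance(Vx, Vy),
            wavelet_covariance(Vx, Vx),
            wavelet_covariance(Vy, Vy),
        )
        limit = (
            cov.correlation()[0, 1]
            * asymptotic_beta(ax, ay)
            / np.sqrt(asymptotic_beta(ax, ax) * asymptotic_beta(ay, ay))
        )
        # scales 4..7: coarse enough for the limit, enough coefficients left
        assert np.nanmean(d[3:7]) == pytest.approx(limit, abs=0.2)


class TestAsymptoticBeta:
    def test_white_noise_value_is_one(self):
        assert asymptotic_beta(0.0, 0.0) == 1.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.floats(-0.45, 0.45, allow_nan=False),
        st.floats(-0.45, 0.45, allow_nan=False),
    )
    def test_symmetric_in_arguments(self, ax, ay):
        assert asymptotic_beta(ax, ay) == pytest.approx(
            asymptotic_beta(ay, ax), rel=1e-14
        )

    @pytest.mark.parametrize(
        "ax,ay", [(0.3, 0.3), (0.1, 0.4), (-0.2, 0.3), (0.0, 0.0)]
    )
    def test_matches_octave_band_average_oracle(self, ax, ay):
        # oracle: beta = lim_q 2^-q(ax+ay) * 2^q * 2 int_band Re[(1-e^{jf})^-ax
        # (1-e^{-jf})^-ay] df / (2 pi), evaluated by quadrature at q = 18
        q = 18
        lo, hi = 2 * np.pi / 2 ** (q + 1), 2 * np.pi / 2**q
        re, _ = quad(
            lambda f: (
                (1 - np.exp(1j * f)) ** (-ax) * (1 - np.exp(-1j * f)) ** (-ay)
            ).real
            / (2 * np.pi),
            lo,
            hi,
            limit=400,
        )
        oracle = 2**q * 2 * re / 2 ** (q * (ax + ay))
        assert asymptotic_beta(ax, ay) == pytest.approx(oracle, rel=1e-4)

    def test_frozen_reference_value(self):
        # band-average oracle at (0.3, 0.3), frozen from the quadrature above
        assert asymptotic_beta(0.3, 0.3) == pytest.approx(0.4019126730, abs=1e-9)


class TestMemoryEstimation:
    def test_white_noise_estimate_near_zero(self):
        ests = [
            estimate_memory_parameter(
                np.random.default_rng(s).standard_normal(2048)
            ).a_hat
            for s in range(10)
        ]
        assert abs(np.mean(ests)) < 0.05

    def test_recovers_strong_memory(self):
        ests = []
        for s in range(5):
            ts = simulate_multivariate_fin(
                MemoryParams([0.4]), ShortMemoryCov([[1.0]]), 4096, seed=s
            )
            ests.append(estimate_memory_parameter(ts.values[:, 0]).a_hat)
        assert 0.35 <= np.mean(ests) <= 0.45

    def test_estimates_order_with_true_exponents(self):
        def mean_est(a):
            vals = []
            for s in range(5):
                ts = simulate_multivariate_fin(
                    MemoryParams([a]), ShortMemoryCov([[1.0]]), 2048, seed=300 + s
                )
                vals.append(estimate_memory_parameter(ts.values[:, 0]).a_hat)
            return np.mean(vals)

        assert mean_est(0.1) < mean_est(0.4)

    def test_innovation_variance_recovered(self):
        ts = simulate_multivariate_fin(
            MemoryParams([0.3]), ShortMemoryCov([[2.5]]), 4096, seed=9
        )
        est = estimate_memory_parameter(ts.values[:, 0])
        assert est.eta_hat_diag == pytest.approx(2.5, rel=0.15)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_memory_parameter(np.ones(128))

    def test_antipersistent_series_hits_no_boundary(self, rng):
        x = np.diff(rng.standard_normal(1025))  # differenced noise: a = -1 truncated
        est = estimate_memory_parameter(x)
        assert est.a_hat <= -0.3  # strongly antipersistent
        assert est.at_boundary  # clipped range cannot represent a <= -0.49


class TestShortMemoryCov:
    @pytest.mark.parametrize("ax", [-0.4, -0.2, 0.0, 0.2, 0.4])
    @pytest.mark.parametrize("ay", [-0.4, -0.2, 0.0, 0.2, 0.4])
    def test_noiseless_power_law_round_trip(self, ax, ay):
        eta = 0.7
        q = np.arange(1, 8)
        ups = ScaleCovariances(
            eta * asymptotic_beta(ax, ay) * 2.0 ** (q * (ax + ay)), tuple([64] * 7)
        )
        assert estimate_short_memory_cov(ups, ax, ay) == pytest.approx(
            eta, abs=1e-10
        )

    def test_negative_covariance_sign_preserved(self):
        ax, ay, eta = 0.2, 0.3, -0.45
        q = np.arange(1, 8)
        ups = ScaleCovariances(
            eta * asymptotic_beta(ax, ay) * 2.0 ** (q * (ax + ay)), tuple([64] * 7)
        )
        assert estimate_short_memory_cov(ups, ax, ay) == pytest.approx(
            eta, abs=1e-10
        )

    def test_white_noise_collapses_to_sample_covariance(self, rng):
        x = rng.standard_normal((4096, 2))
        x[:, 1] = 0.6 * x[:, 0] + 0.8 * x[:, 1]
        # shallow depth: every scale keeps >= 64 coefficients, so the
        # log-scale average is dominated by estimation, not scale noise
        Vx, Vy = wavelet_decompose(x[:, 0], Q=6), wavelet_decompose(x[:, 1], Q=6)
        ups = wavelet_covariance(Vx, Vy)
        eta = estimate_short_memory_cov(ups, 0.0, 0.0)
        sample = float(np.cov(x.T, bias=True)[0, 1])
        assert eta == pytest.approx(sample, abs=0.08)

    def test_bivariate_fin_recovery(self, bivariate_fin):
        ts, params, cov = bivariate_fin
        Vx = wavelet_decompose(ts.values[:, 0])
        Vy = wavelet_decompose(ts.values[:, 1])
        ups = wavelet_covariance(Vx, Vy)
        eta = estimate_short_memory_cov(ups, *params.a)
        assert eta == pytest.approx(cov.eta[0, 1], abs=0.15)

    def test_scales_with_undefined_covariance_rejected(self):
        ups = ScaleCovariances(np.array([1.0, np.nan, 0.5]), (8, 4, 2))
        with pytest.raises(ValueError, match="undefined"):
            estimate_short_memory_cov(ups, 0.1, 0.1, q_range=[1, 2, 3])
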