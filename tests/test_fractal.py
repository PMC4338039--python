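"""Tests of the SOC diagnostic battery against independent oracles."""

import numpy as np
import pytest

from kurasoc.fractal import (
    EnvelopeSeries,
    amplitude_envelope,
    ash_density_2d,
    decision_autocorrelation,
    dfa,
    multifractal_spectrum,
    pattern_correlation,
    preference_span,
    welch_slope,
)
from kurasoc.surrogates import (
    binomial_cascade,
    cascade_hurst,
    fractional_gaussian_noise,
    powerlaw_noise,
    white_noise,
)


class TestEnvelope:
    def test_pure_tone_envelope_is_amplitude(self):
        fs = 20.0
        t = np.arange(0, 200, 1 / fs)
        x = 1.7 * np.sin(2 * np.pi * 0.8 * t)
        env = amplitude_envelope(x, fs=fs)
        interior = env.values[200:-200]
        assert np.allclose(interior, 1.7, rtol=0.01)

    def test_am_tone_recovers_modulation(self):
        fs = 20.0
        t = np.arange(0, 400, 1 / fs)
        carrier, fm = 2.0, 0.05
        x = (1 + 0.5 * np.sin(2 * np.pi * fm * t)) * np.sin(2 * np.pi * carrier * t)
        env = amplitude_envelope(x, fs=fs)
        expected = 1 + 0.5 * np.sin(2 * np.pi * fm * t)
        sl = slice(400, -400)
        assert np.allclose(env.values[sl], expected[sl], rtol=0.02)

    def test_constant_phases_give_constant_envelope(self):
        theta = np.tile([0.5, 1.0, 2.0], (500, 1))
        env = amplitude_envelope(theta, fs=20.0)
        assert np.ptp(env.values[50:-50]) < 1e-9

    def test_decimation_halves_rate(self):
        x = np.sin(np.arange(4000) * 0.1)
        env = amplitude_envelope(x, fs=20.0, out_fs=10.0)
        assert env.fs == 10.0
        assert env.values.size == 2000

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            amplitude_envelope(np.zeros(4), fs=20.0)


class TestDFA:
    def test_white_noise_exponent(self):
        x = white_noise(2 ** 20, np.random.default_rng(0))
        res = dfa(x, fit_range=(10, 10 ** 3.5))
        assert res.alpha == pytest.approx(0.5, abs=0.03)
        assert res.beta == pytest.approx(0.0, abs=0.06)
        assert res.r2 > 0.99

    def test_integrated_white_noise_exponent(self):
        x = np.cumsum(white_noise(2 ** 20, np.random.default_rng(0)))
        res = dfa(x, fit_range=(10, 10 ** 3.5))
        assert res.alpha == pytest.approx(1.5, abs=0.05)

    def test_linear_profile_detrended_exactly(self):
        # a series that is constant within each box integrates to a linear
        # profile there, which order-1 detrending removes exactly
        rng = np.random.default_rng(2)
        x = np.repeat(rng.normal(size=256), 16) + 1e-9 * rng.normal(size=256 * 16)
        res = dfa(x, fit_range=(16, 64), fs=1.0)
        assert res.fluctuations[res.box_sizes == 16][0] < 1e-7  # vs O(1) variance

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            dfa(np.ones(4096), fit_range=(10, 100))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dfa(np.random.default_rng(0).normal(size=256), fit_range=(10, 100))

    def test_amplitude_scaling_leaves_exponent_unchanged(self):
        x = white_noise(2 ** 16, np.random.default_rng(3))
        a1 = dfa(x, fit_range=(10, 1000)).alpha
        a2 = dfa(1e4 * x, fit_range=(10, 1000)).alpha
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestWelch:
    def test_white_noise_flat(self):
        x = white_noise(2 ** 18, np.random.default_rng(1))
        res = welch_slope(x, fit_band=(1e-3, 1e-1))
        assert res.beta == pytest.approx(0.0, abs=0.05)

    def test_pink_noise_recovered(self):
        x = powerlaw_noise(2 ** 18, 1.0, np.random.default_rng(2))
        res = welch_slope(x, fit_band=(1e-3, 1e-1))
        assert res.beta == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("hurst", [0.3, 0.5, 0.7, 0.9])
    def test_beta_identity_on_fgn(self, hurst):
        x = fractional_gaussian_noise(2 ** 18, hurst, np.random.default_rng(5))
        beta_psd = welch_slope(x, fit_band=(1e-3, 1e-1)).beta
        alpha = dfa(x, fit_range=(10, 10 ** 3.5)).alpha
        assert beta_psd == pytest.approx(2 * alpha - 1, abs=0.1)

    def test_run_averaging_reduces_variance(self):
        rng = np.random.default_rng(8)
        runs = [powerlaw_noise(2 ** 14, 1.0, rng) for _ in range(10)]
        multi = welch_slope(runs, fit_band=(1e-3, 1e-1))
        single = welch_slope(runs[0], fit_band=(1e-3, 1e-1))
        assert multi.r2 >= single.r2

    def test_band_outside_resolution_rejected(self):
        with pytest.raises(ValueError):
            welch_slope(np.random.default_rng(0).normal(size=4096), fit_band=(1e-6, 1e-1))


class TestMultifractal:
    def test_monofractal_fgn_has_narrow_spectrum(self):
        x = fractional_gaussian_noise(2 ** 16, 0.7, np.random.default_rng(1))
        res = multifractal_spectrum(x)
        assert res.delta_h <= 0.1
        assert np.mean(res.h) == pytest.approx(0.7, abs=0.1)

    def test_binomial_cascade_matches_closed_form(self):
        c = binomial_cascade(14, 0.75, np.random.default_rng(0))
        res = multifractal_spectrum(c)
        theory = cascade_hurst(res.q, 0.75)
        sel = (res.q >= 1) & (res.q <= 5)
        assert np.max(np.abs(res.h - theory)[sel]) < 0.1
        assert res.delta_h > 0.25  # clearly multifractal

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            multifractal_spectrum(np.ones(8192))

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            multifractal_spectrum(np.random.default_rng(0).normal(size=8192), q_grid=np.array([-1.0, 2.0]))

    def test_amplitude_scaling_invariance(self):
        x = fractional_gaussian_noise(2 ** 14, 0.6, np.random.default_rng(4))
        h1 = multifractal_spectrum(x).h
        h2 = multifractal_spectrum(250.0 * x).h
        assert np.allclose(h1, h2, atol=1e-9)


class TestDecisionAutocorrelation:
    def test_constant_series(self):
        n = 50
        lags, gamma, gnorm = decision_autocorrelation(np.ones(n))
        assert np.array_equal(gamma, n - np.abs(lags))
        assert np.allclose(gnorm, 1.0)
        assert gamma[lags == 0][0] == n

    def test_alternating_series_alternates_sign(self):
        d = np.resize([1, -1], 40)
        lags, gamma, _ = decision_autocorrelation(d)
        pos = gamma[lags > 0]
        signs = np.sign(pos[:10])
        assert np.array_equal(signs, np.resize([-1.0, 1.0], 10))

    def test_iid_series_stays_inside_null_band(self):
        rng = np.random.default_rng(0)
        d = rng.choice([-1, 1], size=1000)
        lags, _, gnorm = decision_autocorrelation(d)
        pos = gnorm[lags > 0][:500]
        band = 2.0 / np.sqrt(1000 - np.arange(1, 501))  # per-lag binomial sd
        frac_inside = np.mean(np.abs(pos) < band)
        assert frac_inside >= 0.93  # ~95.4% expected under the null
        assert preference_span(d) <= 2

    def test_persistent_series_has_long_span(self):
        d = np.repeat(np.resize([1, -1], 40), 25)  # preferences of 25 trials
        assert 10 <= preference_span(d) <= 40

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            decision_autocorrelation(np.array([1]))


class TestPatternCorrelation:
    def test_ash_density_normalizes(self, rng):
        x, y = rng.uniform(-1, 1, 2000), rng.uniform(-1, 1, 2000)
        d = ash_density_2d(x, y, bins=50, shifts=4)
        assert d.shape == (50, 50)
        cell = (2.0 / 50) ** 2
        assert d.sum() * cell == pytest.approx(1.0, rel=1e-6)

    def test_matrix_properties(self, rng):
        fs = 10.0
        n = int(500 * fs)
        t = np.arange(n) / fs
        theta = np.column_stack([1.3 * t + rng.normal(0, 0.1, n),
                                 0.7 * t + rng.normal(0, 0.1, n),
                                 t])
        starts, corr = pattern_correlation(theta, fs, window_s=125, slide_s=25)
        assert corr.shape == (starts.size, starts.size)
        assert np.allclose(corr, corr.T, atol=1e-12)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.all(corr <= 1.0 + 1e-12) and np.all(corr >= -1.0 - 1e-12)

    def test_identical_dynamics_correlate_perfectly(self):
        fs = 10.0
        n = int(125 * fs)
        t = np.arange(n) / fs
        block = np.column_stack([0.9 * t, 0.4 * t, 0.1 * t])
        theta = np.vstack([block, block])
        _, corr = pattern_correlation(theta, fs, window_s=125, slide_s=125)
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            pattern_correlation(np.zeros((10, 3)), fs=10.0, window_s=125)


def test_envelope_series_validation():
    with pytest.raises(ValueError):
        EnvelopeSeries(np.zeros((3, 3)), fs=10.0)
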