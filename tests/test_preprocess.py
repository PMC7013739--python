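"""Conditioning chain: Newton resampling, zero-phase band-pass, percentile
normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_signal
from oracles import sorted_percentile_oracle
from pulseaf import (
    ConfigurationError,
    PreprocessConfig,
    SignalError,
    bandpass,
    detect_peaks,
    normalize,
    preprocess,
    resample,
)


class TestResample:
    def test_identity_at_same_rate(self, rng):
        sig = make_signal(rng.normal(size=200), fs=50.0)
        out = resample(sig, 50.0)
        assert out.fs == 50.0
        assert np.array_equal(out.samples, sig.samples)

    def test_constant_stays_constant(self):
        sig = make_signal(np.full(100, 3.7), fs=10.0)
        out = resample(sig, 37.0)
        assert np.allclose(out.samples, 3.7, atol=1e-12)

    def test_sine_upsampled_matches_analytic(self):
        t_in = np.arange(0, 5, 1 / 50)
        sig = make_signal(np.sin(2 * np.pi * t_in), fs=50.0)
        out = resample(sig, 100.0)
        t_out = np.arange(len(out)) / 100.0
        assert np.max(np.abs(out.samples - np.sin(2 * np.pi * t_out))) < 1e-3

    def test_duration_preserved_within_one_sample(self):
        sig = make_signal(np.sin(np.arange(501) / 10.0), fs=50.0)
        out = resample(sig, 80.0)
        assert abs(out.duration - sig.duration) <= 1 / 80.0 + 1e-12

    def test_linearity(self, rng):
        x = rng.normal(size=120)
        y = rng.normal(size=120)
        a, b = 2.5, -1.3
        lhs = resample(make_signal(a * x + b * y, 40.0), 90.0).samples
        rhs = a * resample(make_signal(x, 40.0), 90.0).samples + b * resample(
            make_signal(y, 40.0), 90.0
        ).samples
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(SignalError):
            resample(make_signal([0.0, 1.0, 2.0], 10.0), 20.0)


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = bandpass(make_signal(np.zeros(1000), 100.0), 0.5, 8.0)
        assert np.allclose(out.samples, 0.0)

    def test_stopband_sinusoid_attenuated_20db(self):
        t = np.arange(0, 400, 0.01)
        sig = make_signal(np.sin(2 * np.pi * 0.05 * t), 100.0)
        out = bandpass(sig, 0.5, 8.0, order=4)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        atten = np.max(np.abs(out.samples[mid]))
        assert atten <= 10 ** (-20 / 20)  # >= 20 dB down

    def test_passband_sinusoid_retained(self):
        t = np.arange(0, 60, 0.01)
        sig = make_signal(np.sin(2 * np.pi * 2.0 * t), 100.0)
        out = bandpass(sig, 0.5, 8.0, order=4)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.max(np.abs(out.samples[mid])) >= 0.9

    def test_zero_phase_no_lag(self):
        t = np.arange(0, 60, 0.01)
        x = np.sin(2 * np.pi * 2.0 * t)
        out = bandpass(make_signal(x, 100.0), 0.5, 8.0).samples
        mid = slice(1000, 5000)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[mid], np.roll(out, lag)[mid]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_band_outside_nyquist_rejected(self):
        sig = make_signal(np.zeros(100), 10.0)
        with pytest.raises(ConfigurationError):
            bandpass(sig, 0.5, 6.0)  # high edge above 5 Hz Nyquist
        with pytest.raises(ConfigurationError):
            bandpass(sig, 0.0, 2.0)


class TestNormalize:
    def test_unit_percentile_signal_unchanged(self, rng):
        x = rng.normal(size=1000)
        x /= np.percentile(x, 97)
        out = normalize(make_signal(x, 100.0), 97.0)
        assert np.allclose(out.samples, x)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        x = np.random.default_rng(7).normal(size=500)
        a = normalize(make_signal(x, 100.0)).samples
        b = normalize(make_signal(scale * x, 100.0)).samples
        assert np.allclose(a, b, atol=1e-12)

    def test_ramp_against_sort_oracle(self):
        x = np.linspace(0, 1, 1001)
        out = normalize(make_signal(x, 100.0), 97.0)
        expected_scale = sorted_percentile_oracle(x, 97.0)
        assert np.allclose(out.samples, x / expected_scale)
        assert np.isclose(out.samples.max(), 1.0 / expected_scale * 1.0)

    def test_nonpositive_percentile_value_rejected(self):
        with pytest.raises(SignalError, match="percentile"):
            normalize(make_signal(-np.ones(100), 10.0), 97.0)

    def test_idempotent(self, rng):
        x = rng.normal(size=300)
        once = normalize(make_signal(x, 10.0)).samples
        twice = normalize(make_signal(once, 10.0)).samples
        assert np.allclose(once, twice)

    def test_preserves_local_maxima_locations(self, rng):
        x = np.abs(rng.normal(size=400)) + 0.1
        sig = make_signal(x, 100.0)
        before = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]))
        after_samples = normalize(sig).samples
        after = np.flatnonzero(
            (after_samples[1:-1] > after_samples[:-2]) & (after_samples[1:-1] > after_samples[2:])
        )
        assert np.array_equal(before, after)


class TestPreprocessPipeline:
    def test_output_rate_matches_config(self, nsr_signal):
        wave, _ = nsr_signal
        out = preprocess(wave, PreprocessConfig(target_fs=80.0))
        assert out.fs == 80.0

    def test_peak_count_preserved_on_clean_nsr(self, nsr_signal):
        wave, _ = nsr_signal
        raw_peaks = detect_peaks(wave).n_beats
        pre_peaks = detect_peaks(preprocess(wave)).n_beats
        assert abs(raw_peaks - pre_peaks) <= 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            PreprocessConfig(band_low=5.0, band_high=1.0)
        with pytest.raises(ConfigurationError):
            PreprocessConfig(norm_percentile=0.0)
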