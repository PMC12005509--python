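"""Beer-Lambert conversion, filtering and baseline correction."""

from __future__ import annotations

import numpy as np
import pytest

import nirstack as ns
from nirstack.io import ValidationError
from nirstack.preprocess import FilterSpec, absorbance_change, bandpass, \
    baseline_correct, default_extinction_table, mbll_convert

FS = 10.1725


def _recording_from_intensities(data):
    n_ch = data.shape[0]
    src = {f"S{i}": (float(i), 0.0) for i in range(1, n_ch + 1)}
    det = {f"D{i}": (float(i), 1.0) for i in range(1, n_ch + 1)}
    channels = tuple((f"S{i}", f"D{i}") for i in range(1, n_ch + 1))
    montage = ns.Montage(src, det, channels)
    return ns.RawIntensityRecording(data, (760.0, 850.0), FS, montage)


def _series(dHbO, dHbR, fs=FS):
    return ns.HemoTimeSeries(dHbO, dHbR, dHbO + dHbR, fs)


class TestAbsorbance:
    def test_constant_intensity_gives_zero(self):
        rec = _recording_from_intensities(np.full((2, 50, 2), 1234.5))
        dA = absorbance_change(rec, baseline=(0, 10))
        np.testing.assert_allclose(dA, 0.0, atol=1e-15)

    def test_halved_intensity_gives_log10_two(self):
        data = np.full((1, 40, 2), 1000.0)
        data[:, 20:, :] = 500.0
        rec = _recording_from_intensities(data)
        dA = absorbance_change(rec, baseline=(0, 20))
        np.testing.assert_allclose(dA[:, 20:, :], np.log10(2.0), rtol=1e-12)

    def test_matches_elementwise_log_oracle(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(200, 2000, size=(3, 60, 2))
        rec = _recording_from_intensities(data)
        dA = absorbance_change(rec, baseline=(5, 25))
        ref = data[:, 5:25, :].mean(axis=1, keepdims=True)
        oracle = np.empty_like(data)
        for c in range(3):
            for t in range(60):
                for w in range(2):
                    oracle[c, t, w] = -np.log10(data[c, t, w] / ref[c, 0, w])
        np.testing.assert_allclose(dA, oracle, rtol=1e-12)

    def test_empty_baseline_rejected(self):
        rec = _recording_from_intensities(np.full((1, 30, 2), 1.0))
        with pytest.raises(ValueError):
            absorbance_change(rec, baseline=(10, 10))


class TestMbll:
    def test_zero_absorbance_gives_zero_concentration(self):
        ext = default_extinction_table()
        out = mbll_convert(np.zeros((4, 30, 2)), ext, 3.0, FS)
        np.testing.assert_array_equal(out.dHbO, 0.0)
        np.testing.assert_array_equal(out.dHbT, 0.0)

    def test_identity_alpha_unit_path_is_identity(self):
        ext = ns.ExtinctionTable(np.array([[1.0, 1e-9], [1e-9, 1.0]]),
                                 dpf=1.0, wavelengths_nm=(760.0, 850.0))
        dA = np.zeros((1, 5, 2))
        dA[0, :, 0] = np.arange(5)
        dA[0, :, 1] = 10 + np.arange(5)
        out = mbll_convert(dA, ext, 1.0, FS)
        np.testing.assert_allclose(out.dHbO[0], np.arange(5), atol=1e-6)
        np.testing.assert_allclose(out.dHbR[0], 10 + np.arange(5), atol=1e-6)

    def test_matches_adjugate_inverse_oracle(self):
        a, b, c, d = 0.7, 0.3, 0.2, 0.9
        ext = ns.ExtinctionTable(np.array([[a, b], [c, d]]), dpf=6.0,
                                 wavelengths_nm=(760.0, 850.0))
        rng = np.random.default_rng(9)
        dA = rng.normal(size=(2, 7, 2))
        sep = 3.0
        out = mbll_convert(dA, ext, sep, FS)
        det = a * d - b * c
        inv = np.array([[d, -b], [-c, a]]) / det  # adjugate formula
        for ch in range(2):
            for t in range(7):
                expected = inv @ dA[ch, t] / (sep * 6.0)
                np.testing.assert_allclose(
                    [out.dHbO[ch, t], out.dHbR[ch, t]], expected, rtol=1e-10)

    def test_singular_alpha_raises_with_condition_number(self):
        with pytest.raises(ValidationError, match="condition number"):
            ns.ExtinctionTable(np.array([[1.0, 1.0], [1.0, 1.0 + 1e-12]]),
                               dpf=6.0, wavelengths_nm=(760.0, 850.0))

    def test_forward_inverse_round_trip(self):
        """alpha . dC . l . d forward then mbll_convert recovers dC."""
        ext = default_extinction_table()
        rng = np.random.default_rng(2)
        dC = rng.normal(scale=0.5, size=(20, 61, 2))
        dA = np.einsum("ij,ctj->cti", ext.alpha, dC) * (3.0 * ext.dpf)
        out = mbll_convert(dA, ext, 3.0, FS)
        rec = np.stack([out.dHbO, out.dHbR], axis=-1)
        rel = np.max(np.abs(rec - dC)) / np.max(np.abs(dC))
        assert rel <= 1e-10


class TestBandpass:
    def test_zero_in_zero_out_and_shape(self):
        s = _series(np.zeros((3, 800)), np.zeros((3, 800)))
        out = bandpass(s)
        assert out.dHbO.shape == s.dHbO.shape
        np.testing.assert_allclose(out.dHbO, 0.0, atol=1e-12)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 360, 1 / FS)
        x = np.sin(2 * np.pi * 0.1 * t)[None, :]
        out = bandpass(_series(x, np.zeros_like(x)))
        trim = slice(int(30 * FS), -int(30 * FS))
        gain = np.abs(out.dHbO[0, trim]).max()
        assert 0.9 <= gain <= 1.1

    def test_cardiac_band_attenuated(self):
        t = np.arange(0, 360, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)[None, :]
        out = bandpass(_series(x, np.zeros_like(x)))
        trim = slice(int(30 * FS), -int(30 * FS))
        rms_out = np.sqrt(np.mean(out.dHbO[0, trim] ** 2))
        rms_in = np.sqrt(0.5)
        assert rms_out < 0.1 * rms_in

    def test_linearity(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(2, 900))
        y = rng.normal(size=(2, 900))
        a, b = 2.5, -1.2
        lhs = bandpass(_series(a * x + b * y, np.zeros_like(x))).dHbO
        rhs = a * bandpass(_series(x, np.zeros_like(x))).dHbO \
            + b * bandpass(_series(y, np.zeros_like(y))).dHbO
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_short_series_rejected_with_minimum(self):
        s = _series(np.zeros((1, 10)), np.zeros((1, 10)))
        with pytest.raises(ValidationError, match="at least"):
            bandpass(s)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            FilterSpec(low_cut_hz=0.3, high_cut_hz=0.2)


class TestBaselineCorrect:
    def test_shift_invariance(self, paradigm):
        rng = np.random.default_rng(8)
        n = int(round(360 * FS))
        x = rng.normal(size=(2, n))
        base = baseline_correct(_series(x, -0.3 * x), paradigm)
        shifted = baseline_correct(_series(x + 7.5, -0.3 * x), paradigm)
        np.testing.assert_allclose(shifted.dHbO, base.dHbO, atol=1e-10)

    def test_rest_window_mean_is_zero(self, paradigm):
        rng = np.random.default_rng(1)
        n = int(round(360 * FS))
        x = rng.normal(loc=3.0, size=(3, n))
        out = baseline_correct(_series(x, np.zeros_like(x)), paradigm)
        idx = np.r_[0:int(round(30 * FS)), int(round(330 * FS)):n]
        np.testing.assert_allclose(out.dHbO[:, idx].mean(axis=1), 0.0, atol=1e-10)
        # all samples shifted by the original rest-window mean
        m = x[:, idx].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.dHbO, x - m, atol=1e-10)

    def test_paradigm_longer_than_recording_rejected(self, paradigm):
        s = _series(np.zeros((1, 100)), np.zeros((1, 100)))
        with pytest.raises(ValidationError):
            baseline_correct(s, paradigm)


class TestHemoInvariants:
    def test_dhbt_consistency_enforced(self):
        with pytest.raises(ValidationError):
            ns.HemoTimeSeries(np.ones((1, 5)), np.ones((1, 5)),
                              np.zeros((1, 5)), FS)

    def test_dhbt_preserved_through_full_chain(self, hemo_series):
        np.testing.assert_allclose(
            hemo_series.dHbT, hemo_series.dHbO + hemo_series.dHbR, atol=1e-9)

    def test_shapes_never_change(self, default_recording, paradigm):
        series = ns.preprocess_recording(default_recording, paradigm)
        assert series.dHbO.shape == (default_recording.n_channels,
                                     default_recording.n_samples)
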