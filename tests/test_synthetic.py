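"""Synthetic recording generator: HRF, noise structure, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps
from scipy.special import gammaln

import nirstack as ns
from nirstack.synthetic import canonical_hrf

FS = 10.1725


class TestCanonicalHrf:
    def test_peak_location_and_unit_maximum(self):
        h = canonical_hrf(FS, peak_s=6.0, undershoot_s=16.0)
        assert h.max() == 1.0
        t_peak = h.argmax() / FS
        assert abs(t_peak - 6.0) <= 1.0
        assert len(h) >= int(30 * FS)

    def test_has_late_undershoot(self):
        h = canonical_hrf(FS)
        late = h[int(12 * FS):]
        assert late.min() < 0

    def test_matches_closed_form_double_gamma(self):
        peak, under, ratio = 6.0, 16.0, 1.0 / 6.0
        h = canonical_hrf(FS, peak, under, undershoot_ratio=ratio)
        t = np.arange(len(h)) / FS

        def gpdf(t, shape):
            tt = np.maximum(t, 1e-12)
            out = np.exp((shape - 1) * np.log(tt) - tt - gammaln(shape))
            out[t <= 0] = 0.0
            return out

        raw = gpdf(t, peak + 1) - ratio * gpdf(t, under + 1)
        np.testing.assert_allclose(h, raw / raw.max(), rtol=1e-12)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            canonical_hrf(-1.0)
        with pytest.raises(ValueError):
            canonical_hrf(FS, peak_s=10.0, undershoot_s=5.0)


class TestSimulateHemo:
    def test_noiseless_active_channel_is_scaled_convolution(self):
        cfg = ns.SimulationConfig(noise=ns.NoiseSpec.silent(), trial_gain_sd=0.0,
                                  n_channels=2, active_channel_fraction=0.5,
                                  activation_amp_uM=0.7, seed=4)
        series, boxcar = ns.simulate_hemo(cfg)
        hrf = canonical_hrf(cfg.fs_hz, cfg.hrf_peak_s, cfg.hrf_undershoot_s)
        expected = np.convolve(boxcar, hrf)[:series.n_samples] * 0.7
        active = int(np.argmax(np.abs(series.dHbO).max(axis=1)))
        np.testing.assert_allclose(series.dHbO[active], expected, atol=1e-12)
        np.testing.assert_allclose(series.dHbR[active], expected * cfg.hbr_ratio,
                                   atol=1e-12)
        other = 1 - active
        np.testing.assert_array_equal(series.dHbO[other], 0.0)

    def test_boxcar_matches_schedule_arithmetic(self):
        series, boxcar = ns.simulate_hemo(ns.SimulationConfig(seed=0))
        # ten blocks; each block has 101-102 samples of the non-integer rate
        edges = np.flatnonzero(np.diff(np.r_[0.0, boxcar, 0.0]))
        starts, stops = edges[::2], edges[1::2]
        assert len(starts) == 10
        lengths = stops - starts
        assert set(lengths.tolist()) <= {101, 102}
        assert boxcar.sum() == pytest.approx(10 * 10 * FS, abs=10)

    def test_null_amplitude_has_no_class_signal(self):
        cfg = ns.SimulationConfig(activation_amp_uM=0.0, seed=6)
        series, boxcar = ns.simulate_hemo(cfg)
        task = series.dHbO[:, boxcar.astype(bool)]
        rest = series.dHbO[:, ~boxcar.astype(bool)]
        ratio = (task ** 2).mean() / (rest ** 2).mean()
        assert 0.8 < ratio < 1.25

    def test_seed_determinism_byte_identical(self):
        a, _ = ns.simulate_hemo(ns.SimulationConfig(seed=123))
        b, _ = ns.simulate_hemo(ns.SimulationConfig(seed=123))
        assert a.dHbO.tobytes() == b.dHbO.tobytes()
        assert a.dHbR.tobytes() == b.dHbR.tobytes()

    def test_cardiac_only_spectrum_peaks_at_configured_frequency(self):
        cfg = ns.SimulationConfig(
            activation_amp_uM=0.0, trial_gain_sd=0.0,
            noise=ns.NoiseSpec(cardiac_amp=0.5, cardiac_hz=1.1,
                               respiration_amp=0.0, mayer_amp=0.0,
                               white_sd=0.0, drift_amp=0.0),
            seed=2)
        series, _ = ns.simulate_hemo(cfg)
        f, p = sps.periodogram(series.dHbO[0], fs=cfg.fs_hz)
        assert abs(f[np.argmax(p)] - 1.1) < 0.02

    def test_task_raises_hbo_and_lowers_hbr_on_active_channels(self):
        cfg = ns.SimulationConfig(seed=3)
        series, boxcar = ns.simulate_hemo(cfg)
        # response lags the boxcar; compare delayed task windows to rest
        shift = int(round(4.0 * cfg.fs_hz))
        mask = np.r_[np.zeros(shift, bool), boxcar.astype(bool)[:-shift]]
        delta = series.dHbO[:, mask].mean(axis=1) - series.dHbO[:, ~mask].mean(axis=1)
        top = np.argsort(delta)[-5:]
        assert np.all(delta[top] > 0)
        delta_r = series.dHbR[:, mask].mean(axis=1) - series.dHbR[:, ~mask].mean(axis=1)
        assert np.all(delta_r[top] < 0)


class TestSimulateRaw:
    def test_round_trip_through_converter(self, paradigm):
        cfg = ns.SimulationConfig(seed=5)
        truth, _ = ns.simulate_hemo(cfg)
        rec = ns.simulate_raw(cfg)
        ext = ns.default_extinction_table()
        dA = ns.absorbance_change(rec)
        out = ns.mbll_convert(dA, ext, 3.0, cfg.fs_hz)
        # absorbance is taken against the initial-rest mean, so recovery is
        # exact up to that per-channel constant
        offs = (out.dHbO - truth.dHbO).mean(axis=1, keepdims=True)
        rel = np.max(np.abs(out.dHbO - offs - truth.dHbO)) / np.max(np.abs(truth.dHbO))
        assert rel <= 1e-8

    def test_zero_concentration_gives_constant_intensity(self):
        cfg = ns.SimulationConfig(activation_amp_uM=0.0,
                                  noise=ns.NoiseSpec.silent(),
                                  trial_gain_sd=0.0, seed=0)
        rec = ns.simulate_raw(cfg, baseline_intensity=1234.0)
        np.testing.assert_allclose(rec.intensities, 1234.0, rtol=1e-12)

    def test_deterministic_under_seed(self):
        a = ns.simulate_raw(ns.SimulationConfig(seed=9))
        b = ns.simulate_raw(ns.SimulationConfig(seed=9))
        assert a.intensities.tobytes() == b.intensities.tobytes()


class TestSimulateCohort:
    def test_distinct_subject_ids(self):
        recs = ns.simulate_cohort(5, ns.SimulationConfig(seed=1))
        ids = [r.subject_id for r in recs]
        assert len(set(ids)) == 5

    def test_zero_between_subject_sd_shares_amplitude(self):
        _, amps = ns.simulate_cohort(4, ns.SimulationConfig(seed=2),
                                     between_subject_sd=0.0,
                                     return_amplitudes=True)
        assert np.ptp(amps) == 0.0

    def test_amplitude_mean_converges_to_config(self):
        cfg = ns.SimulationConfig(seed=3)
        sd = 0.02
        _, amps = ns.simulate_cohort(200, cfg, between_subject_sd=sd,
                                     return_amplitudes=True)
        se = sd / np.sqrt(200)
        assert abs(amps.mean() - cfg.activation_amp_uM) < 3 * se

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ns.simulate_cohort(2, ns.SimulationConfig(seed=0),
                               between_subject_sd=-0.1)
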