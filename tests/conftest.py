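"""Shared fixtures: small synthetic recordings and pre-trained extractors.

Session scope keeps the expensive pieces (network training) to one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import nirstack as ns


@pytest.fixture(scope="session")
def paradigm() -> ns.Paradigm:
    return ns.Paradigm()


@pytest.fixture(scope="session")
def montage() -> ns.Montage:
    return ns.motor_cortex_20ch()


@pytest.fixture(scope="session")
def silent_cfg() -> ns.SimulationConfig:
    """Noise-free, jitter-free single-channel-activation config."""
    return ns.SimulationConfig(
        noise=ns.NoiseSpec.silent(), trial_gain_sd=0.0,
        active_channel_fraction=0.05, seed=42,
    )


@pytest.fixture(scope="session")
def default_recording() -> ns.RawIntensityRecording:
    return ns.simulate_raw(ns.SimulationConfig(seed=7), subject_id="fix-01")


@pytest.fixture(scope="session")
def hemo_series(default_recording, paradigm) -> ns.HemoTimeSeries:
    return ns.preprocess_recording(default_recording, paradigm)


@pytest.fixture(scope="session")
def epochs(hemo_series, paradigm) -> ns.EpochSet:
    return ns.make_epochs(hemo_series, paradigm, subject_id="fix-01")


@pytest.fixture(scope="session")
def split(epochs):
    return ns.split_epochs(epochs, seed=3)


@pytest.fixture(scope="session")
def separable_split(paradigm):
    """Epochs from a high-SNR recording: classes are easily separable."""
    cfg = ns.SimulationConfig(
        activation_amp_uM=1.0, trial_gain_sd=0.1,
        noise=ns.NoiseSpec(cardiac_amp=0.1, respiration_amp=0.05,
                           mayer_amp=0.05, white_sd=0.1, drift_amp=0.05),
        seed=21,
    )
    rec = ns.simulate_raw(cfg, subject_id="sep-01")
    series = ns.preprocess_recording(rec, paradigm)
    ep = ns.make_epochs(series, paradigm, subject_id="sep-01").balance(seed=0)
    return ns.split_epochs(ep, seed=5)


@pytest.fixture(scope="session")
def trained_extractors(separable_split):
    """One fitted extractor per architecture, trained on the separable split."""
    train, test = separable_split
    out = {}
    for arch in ("cnn1d", "lstm", "bilstm"):
        out[arch] = ns.train_extractor(arch, train, val=test,
                                       max_epochs=25, patience=6, seed=11)
    return out


@pytest.fixture(scope="session")
def fused_features(trained_extractors, separable_split):
    train, test = separable_split
    tr = ns.fuse_features(*(trained_extractors[a].feature_matrix(train)
                            for a in ("cnn1d", "lstm", "bilstm")))
    te = ns.fuse_features(*(trained_extractors[a].feature_matrix(test)
                            for a in ("cnn1d", "lstm", "bilstm")))
    return tr, te
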