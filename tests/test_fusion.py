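"""Feature fusion, FFT transform, stack classifier and command mapping."""

from __future__ import annotations

import numpy as np
import pytest

import nirstack as ns
from nirstack.extractors import FeatureMatrix
from nirstack.io import ValidationError


def _fm(values, labels=None, source="cnn"):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = np.array(["task", "rest"] * (len(values) // 2 + 1),
                          dtype=object)[:len(values)]
    return FeatureMatrix(values, labels, source)


def _brute_dft(row):
    """O(n^2) DFT oracle, independent of numpy's FFT."""
    n = len(row)
    out = np.zeros(n, dtype=complex)
    for k in range(n):
        for j in range(n):
            out[k] += row[j] * np.exp(-2j * np.pi * k * j / n)
    return out


class TestFuse:
    def test_three_32_blocks_give_96_in_order(self):
        rng = np.random.default_rng(0)
        labels = np.array(["task"] * 3 + ["rest"] * 3, dtype=object)
        blocks = [_fm(rng.normal(size=(6, 32)), labels, s)
                  for s in ("cnn", "lstm", "bilstm")]
        fused = ns.fuse_features(*blocks)
        assert fused.values.shape == (6, 96)
        assert fused.source == "fused"
        np.testing.assert_array_equal(fused.values[:, :32], blocks[0].values)
        np.testing.assert_array_equal(fused.values[:, 32:64], blocks[1].values)
        np.testing.assert_array_equal(fused.values[:, 64:], blocks[2].values)

    def test_label_mismatch_names_first_disagreeing_row(self):
        labels_a = np.array(["task", "rest"], dtype=object)
        labels_b = np.array(["task", "task"], dtype=object)
        a = _fm(np.zeros((2, 32)), labels_a)
        b = _fm(np.zeros((2, 32)), labels_b, "lstm")
        c = _fm(np.zeros((2, 32)), labels_a, "bilstm")
        with pytest.raises(ValidationError, match="row 1"):
            ns.fuse_features(a, b, c)

    def test_row_count_mismatch_rejected(self):
        a = _fm(np.zeros((3, 32)))
        b = _fm(np.zeros((2, 32)), source="lstm")
        with pytest.raises(ValidationError, match="mismatch"):
            ns.fuse_features(a, a, b)


class TestFftTransform:
    def test_output_width_49_for_96_inputs(self):
        fused = _fm(np.random.default_rng(0).normal(size=(4, 96)), source="fused")
        out = ns.fft_transform(fused)
        assert out.values.shape == (4, 49)
        assert out.source == "fused_fft"

    def test_constant_row_is_dc_only(self):
        c = 2.5
        fused = _fm(np.full((1, 96), c), np.array(["task"], dtype=object), "fused")
        out = ns.fft_transform(fused)
        assert out.values[0, 0] == pytest.approx(96 * c)
        np.testing.assert_allclose(out.values[0, 1:], 0.0, atol=1e-9)

    def test_integer_cosine_localizes_to_its_bin(self):
        k = 7
        j = np.arange(96)
        row = np.cos(2 * np.pi * k * j / 96)
        out = ns.fft_transform(_fm(row[None, :], np.array(["task"], dtype=object),
                                   "fused"))
        assert out.values[0, k] == pytest.approx(48.0, rel=1e-9)
        others = np.delete(out.values[0], k)
        assert np.max(others) < 1e-9

    def test_magnitudes_match_brute_force_dft(self):
        rng = np.random.default_rng(3)
        row = rng.normal(size=96)
        out = ns.fft_transform(_fm(row[None, :], np.array(["rest"], dtype=object),
                                   "fused"))
        oracle = np.abs(_brute_dft(row))[:49]
        np.testing.assert_allclose(out.values[0], oracle, rtol=1e-9)

    def test_parseval_identity(self):
        rng = np.random.default_rng(4)
        row = rng.normal(size=96)
        full = _brute_dft(row)
        assert np.sum(np.abs(full) ** 2) / 96 == pytest.approx(
            np.sum(row ** 2), rel=1e-9)
        # the rFFT magnitudes reconstruct the full-spectrum power
        mags = ns.FFTFeatureTransform().fit(row[None, :]).transform(row[None, :])[0]
        power = mags[0] ** 2 + mags[-1] ** 2 + 2 * np.sum(mags[1:-1] ** 2)
        assert power / 96 == pytest.approx(np.sum(row ** 2), rel=1e-9)

    def test_added_sinusoid_changes_only_its_bin(self):
        rng = np.random.default_rng(5)
        row = rng.normal(size=96)
        k = 11
        j = np.arange(96)
        bumped = row + 0.7 * np.cos(2 * np.pi * k * j / 96)
        t = ns.FFTFeatureTransform()
        base = np.abs(_brute_dft(row))
        new = np.abs(_brute_dft(bumped))
        changed = np.flatnonzero(np.abs(new - base) > 1e-9)
        assert set(changed) <= {k, 96 - k}
        a = t.fit(row[None, :]).transform(row[None, :])
        b = t.transform(bumped[None, :])
        changed_r = np.flatnonzero(np.abs(a[0] - b[0]) > 1e-9)
        assert set(changed_r) <= {k}

    def test_ablation_options_change_width(self):
        x = np.random.default_rng(6).normal(size=(3, 96))
        assert ns.FFTFeatureTransform(keep_all_bins=True).fit(x).transform(x).shape \
            == (3, 96)
        assert ns.FFTFeatureTransform(include_phase=True).fit(x).transform(x).shape \
            == (3, 98)

    def test_non_finite_rejected(self):
        x = np.full((1, 96), np.nan)
        with pytest.raises(ValidationError):
            ns.FFTFeatureTransform().fit(x)


class TestStackedClassifier:
    def test_separable_fused_features_reach_sanity_floor(self, fused_features):
        tr, te = fused_features
        clf = ns.StackedDenseClassifier(max_epochs=200, patience=20, seed=0)
        clf.fit(tr.values, tr.y(), validation=(te.values, te.y()))
        acc = (clf.predict(te.values) == te.y()).mean()
        assert acc >= 0.9

    def test_shuffled_labels_fall_in_chance_band(self):
        # label-free gaussian features: the only attainable skill is chance;
        # a large balanced test set keeps the band tight
        rng = np.random.default_rng(1)
        x_train, x_test = rng.normal(size=(200, 96)), rng.normal(size=(100, 96))
        y_train = rng.permutation(np.repeat([0, 1], 100))
        y_test = np.repeat([0, 1], 50)
        clf = ns.StackedDenseClassifier(max_epochs=100, patience=None, seed=2)
        clf.fit(x_train, y_train)
        acc = (clf.predict(x_test) == y_test).mean()
        assert 0.35 <= acc <= 0.65

    def test_input_width_contract(self, fused_features):
        tr, _ = fused_features
        clf = ns.StackedDenseClassifier(input_width=49)
        with pytest.raises(ValidationError, match="input_width"):
            clf.fit(tr.values, tr.y())

    def test_width_mismatch_at_predict_rejected(self, fused_features):
        tr, _ = fused_features
        clf = ns.StackedDenseClassifier(max_epochs=2, patience=None, seed=0)
        clf.fit(tr.values, tr.y())
        with pytest.raises(ValidationError):
            clf.predict(np.zeros((2, 49)))

    def test_predict_is_deterministic_and_scores_normalized(self, fused_features):
        tr, te = fused_features
        clf = ns.StackedDenseClassifier(max_epochs=5, patience=None, seed=0)
        clf.fit(tr.values, tr.y())
        labels_a, scores_a = ns.predict(clf, te)
        labels_b, scores_b = ns.predict(clf, te)
        np.testing.assert_array_equal(labels_a, labels_b)
        assert scores_a.tobytes() == scores_b.tobytes()
        np.testing.assert_allclose(scores_a.sum(axis=1), 1.0, rtol=1e-9)

    def test_perfectly_fit_toy_set_reproduces_training_labels(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-3, 0.1, size=(10, 6)),
                            rng.normal(3, 0.1, size=(10, 6))])
        y = np.array([0] * 10 + [1] * 10)
        clf = ns.StackedDenseClassifier(max_epochs=300, patience=None,
                                        learning_rate=0.01, seed=0)
        clf.fit(x, y)
        np.testing.assert_array_equal(clf.predict(x), y)

    def test_fused_width_is_96(self, fused_features):
        tr, te = fused_features
        assert tr.n_features == 96 and te.n_features == 96


class TestCommands:
    def test_mapping_and_length(self):
        assert ns.emit_commands(["task", "rest", "task"]) == \
            ["hand-close", "hand-open", "hand-close"]
        assert ns.emit_commands([]) == []
        assert len(ns.emit_commands([1, 0, 1, 1])) == 4

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            ns.emit_commands(["task", "jump"])
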