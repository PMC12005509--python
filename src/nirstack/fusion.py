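"""Feature fusion and the two proposed classification routes.

The *stack* route concatenates the three 32-dim extractor feature blocks
into a 96-vector and trains a small dense network (64-64-2) on it.  The
*fft* route first applies a real-input discrete Fourier transform along
the 96 feature positions and classifies the 49 non-negative-frequency
magnitudes with the same dense network.  Per-feature z-scoring (fit on
training rows) precedes the dense network by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .extractors import FeatureMatrix
from .io import ValidationError

__all__ = [
    "FFTFeatureTransform",
    "StackedDenseClassifier",
    "fuse_features",
    "fft_transform",
    "train_stack",
    "predict",
    "emit_commands",
]


def fuse_features(cnn: FeatureMatrix, lstm: FeatureMatrix,
                  bilstm: FeatureMatrix) -> FeatureMatrix:
    """Row-wise concatenation in fixed order [cnn | lstm | bilstm].

    Inputs must have equal row counts and aligned labels; the fused width
    is the sum of the block widths (96 for three 32-dim blocks).
    """
    blocks = (cnn, lstm, bilstm)
    n = cnn.values.shape[0]
    for blk in blocks[1:]:
        if blk.values.shape[0] != n:
            raise ValidationError(
                f"row-count mismatch: {n} vs {blk.values.shape[0]} ({blk.source})"
            )
    for row in range(n):
        labs = {blk.labels[row] for blk in blocks}
        if len(labs) != 1:
            raise ValidationError(f"label mismatch at row {row}: {sorted(labs)}")
    values = np.concatenate([blk.values for blk in blocks], axis=1)
    return FeatureMatrix(values, cnn.labels, "fused")


class FFTFeatureTransform(TransformerMixin, BaseEstimator):
    """DFT along the feature axis; emits magnitude spectra.

    By default the real-input transform's non-negative-frequency bins
    (``width // 2 + 1``, i.e. 49 for 96 inputs).  ``keep_all_bins`` keeps
    all ``width`` magnitude bins and ``include_phase`` appends the phases,
    both for ablation experiments.
    """

    def __init__(self, keep_all_bins: bool = False, include_phase: bool = False) -> None:
        self.keep_all_bins = keep_all_bins
        self.include_phase = include_phase

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _validate(X) -> np.ndarray:
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        if values.ndim != 2 or values.shape[1] < 2:
            raise ValidationError("need a 2D feature matrix with width >= 2")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite feature values")
        return values

    def transform(self, X):
        values = self._validate(X)
        if self.keep_all_bins:
            spec = np.fft.fft(values, axis=1)
        else:
            spec = np.fft.rfft(values, axis=1)
        out = np.abs(spec)
        if self.include_phase:
            out = np.concatenate([out, np.angle(spec)], axis=1)
        if isinstance(X, FeatureMatrix):
            return FeatureMatrix(out, X.labels, "fused_fft")
        return out

    @staticmethod
    def output_width(input_width: int) -> int:
        return input_width // 2 + 1


def fft_transform(fused: FeatureMatrix, **kwargs) -> FeatureMatrix:
    """Functional form of :class:`FFTFeatureTransform` on a fused matrix."""
    return FFTFeatureTransform(**kwargs).fit(fused).transform(fused)


class StackedDenseClassifier(ClassifierMixin, BaseEstimator):
    """The stack model: dense 64 -> 64 -> 2 over fused (or FFT) features.

    Trained with Adam (learning rate 1e-4), batch 32 and categorical
    cross-entropy, mirroring the extractor regime.  ``standardize`` fits a
    per-feature z-score on the training rows before the network; without
    it the heterogeneous scales of DFT bins dominate the early training.
    """

    def __init__(self, hidden: tuple[int, int] = (64, 64),
                 learning_rate: float = 1e-4, batch_size: int = 32,
                 max_epochs: int = 100, patience: int | None = 10,
                 standardize: bool = True, output_activation: str = "linear",
                 input_width: int | None = None, seed: int = 0) -> None:
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.standardize = standardize
        self.output_activation = output_activation
        self.input_width = input_width
        self.seed = seed

    @staticmethod
    def _values_labels(X, y):
        if isinstance(X, FeatureMatrix):
            return X.values, X.y() if y is None else np.asarray(y)
        if y is None:
            raise ValidationError("y is required when X is a plain array")
        return np.asarray(X, dtype=float), np.asarray(y)

    def fit(self, X, y=None, validation=None):
        values, y = self._values_labels(X, y)
        if values.ndim != 2:
            raise ValidationError("X must be 2D (epochs x features)")
        if self.input_width is not None and values.shape[1] != self.input_width:
            raise ValidationError(
                f"feature width {values.shape[1]} does not match the configured "
                f"input_width {self.input_width}"
            )
        if len(np.unique(y)) < 2:
            raise ValidationError("training set must contain both classes")
        if tuple(self.hidden) != (64, 64):
            raise ValidationError("the stack model fixes two hidden layers of 64 units")
        self.classes_ = np.unique(y)
        self.n_features_in_ = values.shape[1]
        if self.standardize:
            self.mean_ = values.mean(axis=0)
            sd = values.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(values.shape[1])
            self.scale_ = np.ones(values.shape[1])
        xt = (values - self.mean_) / self.scale_
        layers = [nn.Dense(self.hidden[0], activation="relu"),
                  nn.Dense(self.hidden[1], activation="relu"),
                  nn.Dense(2)]
        self.model_ = nn.Sequential(layers, n_classes=2,
                                    output_activation=self.output_activation)
        self.model_.build((values.shape[1],), seed=self.seed)
        val = None
        if validation is not None:
            vx, vy = validation
            vvals = vx.values if isinstance(vx, FeatureMatrix) else np.asarray(vx, dtype=float)
            vy = vx.y() if (vy is None and isinstance(vx, FeatureMatrix)) else np.asarray(vy)
            val = ((vvals - self.mean_) / self.scale_, vy)
        self.history_ = self.model_.fit(
            xt, y, validation=val, lr=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            patience=self.patience,
        )
        return self

    def _check(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        if values.ndim != 2 or values.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected width {self.n_features_in_}, got {values.shape[1:]}"
            )
        return (values - self.mean_) / self.scale_

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(self._check(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def train_stack(features: FeatureMatrix, spec_kwargs: dict | None = None,
                split: tuple[np.ndarray, np.ndarray] | None = None,
                seed: int = 0) -> tuple[StackedDenseClassifier, dict]:
    """Train the stack model on fused or FFT-transformed features.

    ``split`` gives (train row indices, test row indices); the test rows
    serve as the validation curve recorded in the history.
    """
    kwargs = dict(spec_kwargs or {})
    kwargs.setdefault("seed", seed)
    clf = StackedDenseClassifier(**kwargs)
    y = features.y()
    if split is None:
        clf.fit(features.values, y)
    else:
        tr, te = split
        clf.fit(features.values[tr], y[tr],
                validation=(features.values[te], y[te]))
    return clf, clf.history_


def predict(model: StackedDenseClassifier, features: FeatureMatrix | np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax) and softmax scores, deterministic."""
    scores = model.predict_proba(features)
    return model.classes_[scores.argmax(axis=1)], scores


_COMMAND = {"task": "hand-close", "rest": "hand-open", 1: "hand-close", 0: "hand-open"}


def emit_commands(labels) -> list[str]:
    """Map a predicted label stream onto prosthetic hand commands.

    task -> hand-close, rest -> hand-open; stream length is preserved.  No
    hardware I/O happens here -- the caller owns the transport.
    """
    try:
        return [_COMMAND[lab] for lab in labels]
    except KeyError as exc:
        raise ValidationError(f"unknown label {exc} in command stream")
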