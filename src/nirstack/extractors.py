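"""Deep feature extractors: 1D-CNN, LSTM and Bi-LSTM estimators.

Each network classifies task-vs-rest epochs and, once trained, exposes the
activations of its 32-unit penultimate dense layer as the epoch's feature
vector.  All three share the same tail (max-pool 2, batch normalization,
flatten, dropout 0.2, dense 32 ReLU, dense 2) and the same training regime
(Adam, learning rate 1e-4, batch 32, categorical cross-entropy).

The classes follow the scikit-learn estimator protocol: ``fit(X, y)`` with
``X`` of shape ``(n_epochs, n_channels, window_len)``, ``transform`` for
the 32-dim features, ``predict``/``predict_proba`` for the network's own
classification head.  Epochs enter the networks time-first: the sequence
axis is time, with one input feature per fNIRS channel per step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .epoching import EpochSet
from .io import ValidationError

__all__ = [
    "ExtractorSpec",
    "FeatureMatrix",
    "BaseDeepFeatureExtractor",
    "CNNFeatureExtractor",
    "LSTMFeatureExtractor",
    "BiLSTMFeatureExtractor",
    "make_extractor",
    "build_extractor",
    "train_extractor",
    "extract_features",
]

ARCHS = ("cnn1d", "lstm", "bilstm")


@dataclass(frozen=True)
class ExtractorSpec:
    """Hyperparameters shared by the three extractor networks."""

    arch: str = "cnn1d"
    conv_filters: int = 64
    recurrent_units: int = 64
    kernel: int = 2
    pool: int = 2
    dropout_rate: float = 0.2
    feature_units: int = 32
    out_units: int = 2
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    patience: int | None = 10
    output_activation: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValidationError(f"arch must be one of {ARCHS}")
        if self.feature_units != 32:
            raise ValidationError("feature_units is fixed at 32")
        if self.out_units != 2:
            raise ValidationError("out_units is fixed at 2")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")


@dataclass
class FeatureMatrix:
    """Per-epoch feature vectors with aligned labels.

    ``source`` records provenance: one of cnn / lstm / bilstm / fused /
    fused_fft.  Rows follow epoch order.
    """

    values: np.ndarray
    labels: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be 2D (epochs x features)")
        if len(self.labels) != self.values.shape[0]:
            raise ValidationError("one label per feature row required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def y(self) -> np.ndarray:
        return (self.labels == "task").astype(int)


def _min_window_len(spec: ExtractorSpec) -> int:
    if spec.arch == "cnn1d":
        # two valid kernel-k convs then pool
        return 2 * (spec.kernel - 1) + spec.pool
    return spec.pool


def _build_layers(spec: ExtractorSpec) -> list[nn.Layer]:
    tail = [
        nn.MaxPool1D(spec.pool),
        nn.BatchNorm(),
        nn.Flatten(),
        nn.Dropout(spec.dropout_rate),
        nn.Dense(spec.feature_units, activation="relu"),
        nn.Dense(spec.out_units),
    ]
    if spec.arch == "cnn1d":
        head = [nn.Conv1D(spec.conv_filters, spec.kernel),
                nn.Conv1D(spec.conv_filters, spec.kernel)]
    elif spec.arch == "lstm":
        head = [nn.LSTM(spec.recurrent_units), nn.LSTM(spec.recurrent_units)]
    else:
        head = [nn.Bidirectional(spec.recurrent_units),
                nn.Bidirectional(spec.recurrent_units)]
    return head + tail


#: index of the feature layer counted from the end of the layer stack
_FEATURE_LAYER_FROM_END = 1


def build_extractor(spec: ExtractorSpec, input_shape: tuple[int, int]) -> nn.Sequential:
    """Build the untrained network for epochs of (n_channels, window_len).

    The network consumes sequences of length ``window_len`` with
    ``n_channels`` features per step.
    """
    n_channels, window_len = input_shape
    min_len = _min_window_len(spec)
    if window_len < min_len:
        raise ValidationError(
            f"window_len {window_len} too short for arch {spec.arch!r}; "
            f"minimum is {min_len} samples"
        )
    model = nn.Sequential(_build_layers(spec), n_classes=spec.out_units,
                          output_activation=spec.output_activation)
    model.build((window_len, n_channels), seed=spec.seed)
    return model


def _to_sequences(windows: np.ndarray) -> np.ndarray:
    """(n, channels, time) epochs -> (n, time, channels) network input."""
    return np.ascontiguousarray(np.transpose(windows, (0, 2, 1)))


class BaseDeepFeatureExtractor(TransformerMixin, ClassifierMixin, BaseEstimator):
    """Shared fit/transform/predict machinery; subclasses pin the architecture."""

    _arch = "cnn1d"

    def __init__(self, conv_filters: int = 64, recurrent_units: int = 64,
                 kernel: int = 2, pool: int = 2, dropout_rate: float = 0.2,
                 learning_rate: float = 1e-4, batch_size: int = 32,
                 max_epochs: int = 100, patience: int | None = 10,
                 output_activation: str = "linear", seed: int = 0) -> None:
        self.conv_filters = conv_filters
        self.recurrent_units = recurrent_units
        self.kernel = kernel
        self.pool = pool
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.output_activation = output_activation
        self.seed = seed

    def _spec(self) -> ExtractorSpec:
        return ExtractorSpec(
            arch=self._arch, conv_filters=self.conv_filters,
            recurrent_units=self.recurrent_units, kernel=self.kernel,
            pool=self.pool, dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience,
            output_activation=self.output_activation, seed=self.seed,
        )

    @staticmethod
    def _coerce(X) -> tuple[np.ndarray, np.ndarray | None]:
        if isinstance(X, EpochSet):
            return X.windows, X.y()
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValidationError(
                "X must be (n_epochs, n_channels, window_len) or an EpochSet"
            )
        return X, None

    def fit(self, X, y=None, validation=None):
        """Train on epochs; ``validation`` is an optional (X, y) or EpochSet.

        The per-epoch loss/accuracy curves for both splits are stored in
        ``history_``.
        """
        windows, y_auto = self._coerce(X)
        y = y_auto if y is None else np.asarray(y)
        if y is None:
            raise ValidationError("y is required when X is a plain array")
        if len(np.unique(y)) < 2:
            raise ValidationError("training set must contain both classes")
        spec = self._spec()
        self.classes_ = np.unique(y)
        self.input_shape_ = windows.shape[1:]
        self.model_ = build_extractor(spec, self.input_shape_)
        val = None
        if validation is not None:
            if isinstance(validation, EpochSet):
                val = (_to_sequences(validation.windows), validation.y())
            else:
                vx, vy = validation
                val = (_to_sequences(self._coerce(vx)[0]), np.asarray(vy))
        self.history_ = self.model_.fit(
            _to_sequences(windows), y, validation=val,
            lr=spec.learning_rate, batch_size=spec.batch_size,
            max_epochs=spec.max_epochs, patience=spec.patience,
        )
        self.n_features_ = spec.feature_units
        return self

    def _check_input(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        windows, _ = self._coerce(X)
        if windows.shape[1:] != self.input_shape_:
            raise ValidationError(
                f"epoch shape {windows.shape[1:]} does not match the fitted "
                f"shape {self.input_shape_}"
            )
        return _to_sequences(windows)

    def transform(self, X) -> np.ndarray:
        """32-dim penultimate-layer features, inference mode, one row per epoch."""
        seqs = self._check_input(X)
        upto = len(self.model_.layers) - _FEATURE_LAYER_FROM_END
        return self.model_.forward(seqs, train=False, upto=upto)

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(self._check_input(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def feature_matrix(self, epochs: EpochSet) -> FeatureMatrix:
        source = {"cnn1d": "cnn", "lstm": "lstm", "bilstm": "bilstm"}[self._arch]
        return FeatureMatrix(self.transform(epochs), epochs.labels, source)


class CNNFeatureExtractor(BaseDeepFeatureExtractor):
    """Two 1D convolutions (64 filters, kernel 2) over the time axis."""

    _arch = "cnn1d"


class LSTMFeatureExtractor(BaseDeepFeatureExtractor):
    """Two stacked 64-unit LSTM layers returning full sequences."""

    _arch = "lstm"


class BiLSTMFeatureExtractor(BaseDeepFeatureExtractor):
    """Two stacked bidirectional LSTM layers (64 units per direction)."""

    _arch = "bilstm"


_CLASSES = {
    "cnn1d": CNNFeatureExtractor,
    "lstm": LSTMFeatureExtractor,
    "bilstm": BiLSTMFeatureExtractor,
}


def make_extractor(arch: str, **kwargs) -> BaseDeepFeatureExtractor:
    try:
        cls = _CLASSES[arch]
    except KeyError:
        raise ValidationError(f"unknown architecture {arch!r}; expected one of {ARCHS}")
    return cls(**kwargs)


def train_extractor(arch: str, train: EpochSet, val: EpochSet | None = None,
                    **kwargs) -> BaseDeepFeatureExtractor:
    """Convenience wrapper: build and fit an extractor on an EpochSet."""
    est = make_extractor(arch, **kwargs)
    est.fit(train, validation=val)
    return est


def extract_features(trained: BaseDeepFeatureExtractor, epochs: EpochSet) -> FeatureMatrix:
    return trained.feature_matrix(epochs)
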