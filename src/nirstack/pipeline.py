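"""End-to-end orchestration: preprocess, epoch, split, train, evaluate.

``run_subject`` takes one raw recording through a chosen method; the three
conventional networks (cnn/lstm/bilstm) classify with their own heads,
while the two proposed methods fuse the 96 extractor features and classify
with the stacked dense network, the fft variant after a DFT-magnitude
transform of the fused vector.  ``run_cohort`` repeats per subject
(matching the subject-wise reporting of the target study) and aggregates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .epoching import make_epochs, split_epochs
from .evaluation import EvaluationReport
from .extractors import make_extractor
from .fusion import FFTFeatureTransform, StackedDenseClassifier, fuse_features
from .io import Paradigm, RawIntensityRecording, ValidationError
from .preprocess import FilterSpec, preprocess_recording

__all__ = ["RunConfig", "METHODS", "run_subject", "run_subject_all",
           "run_cohort", "run_cohort_multi"]

METHODS = ("cnn", "lstm", "bilstm", "stack", "fft")
_ARCH_OF = {"cnn": "cnn1d", "lstm": "lstm", "bilstm": "bilstm"}


@dataclass
class RunConfig:
    """Everything a run needs; serializable so runs can be archived and replayed."""

    paradigm: Paradigm = field(default_factory=Paradigm)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    window_s: float = 3.0
    stride_s: float = 3.0
    label_shift_s: float = 2.0
    purity: float = 0.8
    chromophore: str = "HbO"
    test_fraction: float = 0.2
    max_epochs: int = 100
    patience: int | None = 10
    head_max_epochs: int = 300
    head_patience: int | None = 30
    learning_rate: float = 1e-4
    batch_size: int = 32
    standardize_features: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paradigm"] = asdict(self.paradigm)
        d["filter_spec"] = asdict(self.filter_spec)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("paradigm"), dict):
            d["paradigm"] = Paradigm(**d["paradigm"])
        if isinstance(d.get("filter_spec"), dict):
            d["filter_spec"] = FilterSpec(**d["filter_spec"])
        return cls(**d)


def _subject_seed(master_seed: int, subject_id: str, offset: int = 0) -> int:
    # stable across processes (unlike hash())
    h = zlib.crc32(f"{subject_id}:{offset}".encode())
    return int((np.int64(master_seed) * 1009 + h) % (2 ** 31))


def run_subject_all(rec: RawIntensityRecording, cfg: RunConfig,
                    methods: tuple[str, ...] = METHODS,
                    shuffle_labels: bool = False,
                    balance_classes: bool = False) -> dict:
    """Run several methods on one subject, training each extractor once.

    The three conventional networks are trained a single time; their own
    heads give the cnn/lstm/bilstm predictions, and their features feed
    both stack heads.  ``shuffle_labels`` permutes the training labels as a
    chance-level control (test labels stay intact, so accuracy against
    truth is at chance); ``balance_classes`` subsamples epochs to equal
    class counts first, which is what makes the chance level 50%.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValidationError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    series = preprocess_recording(rec, cfg.paradigm, filter_spec=cfg.filter_spec)
    epochs = make_epochs(series, cfg.paradigm, cfg.window_s, cfg.stride_s,
                         cfg.label_shift_s, cfg.purity, cfg.chromophore,
                         rec.subject_id)
    if balance_classes:
        epochs = epochs.balance(seed=_subject_seed(cfg.seed, rec.subject_id, 9))
    train, test = split_epochs(epochs, cfg.test_fraction,
                               seed=_subject_seed(cfg.seed, rec.subject_id, 1))

    y_train = train.y()
    if shuffle_labels:
        rng = np.random.default_rng(_subject_seed(cfg.seed, rec.subject_id, 7))
        y_train = rng.permutation(y_train)

    net_kwargs = dict(max_epochs=cfg.max_epochs, patience=cfg.patience,
                      learning_rate=cfg.learning_rate, batch_size=cfg.batch_size)
    need_fusion = bool({"stack", "fft"} & set(methods))
    archs_needed = [m for m in ("cnn", "lstm", "bilstm")
                    if m in methods or need_fusion]

    histories: dict[str, dict] = {}
    predictions: dict[str, np.ndarray] = {}
    feats_train, feats_test = [], []
    for i, method in enumerate(("cnn", "lstm", "bilstm")):
        if method not in archs_needed:
            continue
        est = make_extractor(_ARCH_OF[method],
                             seed=_subject_seed(cfg.seed, rec.subject_id, 2 + i),
                             **net_kwargs)
        est.fit(train.windows, y_train, validation=test)
        histories[method] = est.history_
        if method in methods:
            predictions[method] = np.asarray(est.predict(test))
        if need_fusion:
            feats_train.append(est.feature_matrix(train))
            feats_test.append(est.feature_matrix(test))

    if need_fusion:
        fused_train = fuse_features(*feats_train)
        fused_test = fuse_features(*feats_test)
        for method in ("stack", "fft"):
            if method not in methods:
                continue
            xt, xe = fused_train, fused_test
            if method == "fft":
                fft = FFTFeatureTransform().fit(fused_train)
                xt, xe = fft.transform(fused_train), fft.transform(fused_test)
            clf = StackedDenseClassifier(
                standardize=cfg.standardize_features,
                max_epochs=cfg.head_max_epochs, patience=cfg.head_patience,
                learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                seed=_subject_seed(cfg.seed, rec.subject_id, 6))
            clf.fit(xt.values, y_train, validation=(xe.values, test.y()))
            histories[f"{method}_head"] = clf.history_
            predictions[method] = np.asarray(clf.predict(xe.values))

    return {
        "subject_id": rec.subject_id,
        "y_true": test.y(),
        "predictions": predictions,
        "histories": histories,
        "n_train": len(train),
        "n_test": len(test),
    }


def run_subject(rec: RawIntensityRecording, cfg: RunConfig, method: str,
                shuffle_labels: bool = False) -> dict:
    """Run one method on one subject; returns predictions and histories."""
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    res = run_subject_all(rec, cfg, methods=(method,), shuffle_labels=shuffle_labels)
    return {
        "subject_id": res["subject_id"],
        "y_true": res["y_true"],
        "y_pred": res["predictions"][method],
        "histories": res["histories"],
        "n_train": res["n_train"],
        "n_test": res["n_test"],
    }


def run_cohort(recordings: list[RawIntensityRecording], cfg: RunConfig,
               method: str, keep_histories: bool = False,
               shuffle_labels: bool = False) -> EvaluationReport:
    """Run one method over a cohort; one report row per subject."""
    return run_cohort_multi(recordings, cfg, methods=(method,),
                            keep_histories=keep_histories,
                            shuffle_labels=shuffle_labels)[method]


def run_cohort_multi(recordings: list[RawIntensityRecording], cfg: RunConfig,
                     methods: tuple[str, ...] = METHODS,
                     keep_histories: bool = False,
                     shuffle_labels: bool = False,
                     balance_classes: bool = False
                     ) -> dict[str, EvaluationReport]:
    """Run several methods over a cohort, sharing extractor training.

    Returns one :class:`EvaluationReport` per method with one row per
    subject, mirroring subject-wise reporting.
    """
    reports = {m: EvaluationReport(method=m) for m in methods}
    for rec in recordings:
        res = run_subject_all(rec, cfg, methods=methods,
                              shuffle_labels=shuffle_labels,
                              balance_classes=balance_classes)
        for m in methods:
            reports[m].add_subject(
                res["subject_id"], res["y_true"], res["predictions"][m],
                histories=res["histories"] if keep_histories else None,
            )
    return reports
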