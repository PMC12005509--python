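"""Cut hemoglobin series into fixed-length labeled task/rest windows.

Window placement and labeling are computed on the continuous-time block
schedule (where the paradigm arithmetic is exact even at a non-integer
sampling rate); samples enter only when extracting window content, with a
single rounding of the start time and a fixed window length in samples.
A window is labeled task when at least ``purity`` of its time interval
overlaps a (optionally delayed) task block, rest when at least ``purity``
lies outside all task blocks, and is discarded otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .io import Paradigm, ValidationError
from .preprocess import HemoTimeSeries

__all__ = ["EpochSet", "make_epochs", "split_epochs"]

TASK, REST = "task", "rest"


@dataclass
class EpochSet:
    """Labeled fixed-length windows: (n_epochs, n_channels, window_len)."""

    windows: np.ndarray
    labels: np.ndarray
    chromophore: str = "HbO"
    window_s: float = 3.0
    stride_s: float = 3.0
    label_shift_s: float = 0.0
    fs_hz: float = 10.1725
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.windows.ndim != 3:
            raise ValidationError("windows must be (n_epochs, n_channels, window_len)")
        if len(self.labels) != self.windows.shape[0]:
            raise ValidationError("one label per epoch required")
        bad = set(self.labels) - {TASK, REST}
        if bad:
            raise ValidationError(f"labels must be 'task' or 'rest'; got {sorted(bad)}")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]

    def y(self) -> np.ndarray:
        """Labels as integers: task=1 (positive class), rest=0."""
        return (self.labels == TASK).astype(int)

    def subset(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(self.windows[idx], self.labels[idx], self.chromophore,
                        self.window_s, self.stride_s, self.label_shift_s,
                        self.fs_hz, self.subject_id)

    def class_counts(self) -> dict[str, int]:
        return {TASK: int((self.labels == TASK).sum()),
                REST: int((self.labels == REST).sum())}

    def balance(self, seed: int = 0) -> "EpochSet":
        """Subsample the majority class to the minority count (for controls
        whose chance level assumes a balanced two-class set)."""
        counts = self.class_counts()
        n_keep = min(counts.values())
        rng = np.random.default_rng(seed)
        keep = []
        for lab in (TASK, REST):
            idx = np.flatnonzero(self.labels == lab)
            keep.append(rng.choice(idx, size=n_keep, replace=False))
        return self.subset(np.sort(np.concatenate(keep)))


def _overlap(a: float, b: float, intervals: list[tuple[float, float]]) -> float:
    """Total length of [a, b) covered by the intervals."""
    return sum(max(0.0, min(b, hi) - max(a, lo)) for lo, hi in intervals)


def make_epochs(series: HemoTimeSeries, paradigm: Paradigm,
                window_s: float = 3.0, stride_s: float = 3.0,
                label_shift_s: float = 2.0, purity: float = 0.8,
                chromophore: str = "HbO", subject_id: str = "unknown") -> EpochSet:
    """Slide labeled windows over the full recording, rest padding included.

    ``label_shift_s`` delays the task blocks before labeling to compensate
    for hemodynamic lag.  With ``purity=1`` any window straddling a
    task/rest boundary is discarded.
    """
    if stride_s <= 0:
        raise ValidationError("stride_s must be positive")
    if not (0.5 < purity <= 1.0):
        raise ValidationError("purity must be in (0.5, 1]")
    data = series.chromophore(chromophore)
    fs = series.fs_hz
    window_len = int(round(window_s * fs))
    if window_len < 1 or window_len > series.n_samples:
        raise ValidationError(
            f"window of {window_len} samples does not fit a recording of "
            f"{series.n_samples} samples"
        )
    task_iv = paradigm.task_intervals_s(label_shift_s)

    starts, labels = [], []
    duration_s = series.n_samples / fs
    k = 0
    while True:
        s0 = k * stride_s
        k += 1
        start = int(round(s0 * fs))
        if start + window_len > series.n_samples or s0 + window_s > duration_s + 0.5 / fs:
            break
        frac_task = _overlap(s0, s0 + window_s, task_iv) / window_s
        if frac_task >= purity - 1e-12:
            labels.append(TASK)
        elif (1.0 - frac_task) >= purity - 1e-12:
            labels.append(REST)
        else:
            continue
        starts.append(start)

    windows = np.stack([data[:, s:s + window_len] for s in starts]) if starts else \
        np.empty((0, series.n_channels, window_len))
    return EpochSet(windows, np.array(labels, dtype=object), chromophore,
                    window_s, stride_s, label_shift_s, fs, subject_id)


def split_epochs(epochs: EpochSet, test_fraction: float = 0.2, seed: int = 0,
                 stratified: bool = True) -> tuple[EpochSet, EpochSet]:
    """Disjoint, exhaustive train/test split of the epochs.

    The stratified variant keeps per-class proportions within one epoch of
    the requested fraction and is deterministic under ``seed``.
    """
    n = len(epochs)
    if n < 2:
        raise ValidationError("need at least 2 epochs to split")
    y = epochs.y()
    if stratified:
        counts = epochs.class_counts()
        missing = [k for k, v in counts.items() if v < 2]
        if missing:
            raise ValidationError(
                f"stratified split needs at least 2 epochs per class; short on {missing}"
            )
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        stratify=y if stratified else None, shuffle=True,
    )
    return epochs.subset(np.sort(train_idx)), epochs.subset(np.sort(test_idx))
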