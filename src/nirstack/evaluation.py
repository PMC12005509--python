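"""Confusion matrices, accuracy/F1 scores, method comparisons and aggregates.

The positive class throughout is motor *activity* (task); confusion
matrices are ordered [activity, rest] on both axes.  Method comparisons
use a paired two-sided t-test across subjects with a Bonferroni-corrected
significance threshold (alpha / number of comparisons); a Wilcoxon
signed-rank alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "confusion",
    "scores",
    "compare_methods",
    "aggregate",
    "EvaluationReport",
    "reference_subject_accuracies",
]

LABEL_ORDER = ("task", "rest")


def _as_str_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "biu":
        return np.where(y.astype(int) == 1, "task", "rest").astype(object)
    return y.astype(object)


def confusion(y_true, y_pred) -> np.ndarray:
    """2x2 count matrix, rows = truth, cols = prediction, order [activity, rest]."""
    yt, yp = _as_str_labels(y_true), _as_str_labels(y_pred)
    if len(yt) != len(yp):
        raise ValidationError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted")
    if len(yt) == 0:
        raise ValidationError("cannot build a confusion matrix from empty inputs")
    bad = (set(yt) | set(yp)) - set(LABEL_ORDER)
    if bad:
        raise ValidationError(f"labels must be task/rest; got {sorted(bad)}")
    mat = np.zeros((2, 2), dtype=int)
    for t, p in zip(yt, yp):
        mat[LABEL_ORDER.index(t), LABEL_ORDER.index(p)] += 1
    return mat


def scores(conf: np.ndarray) -> dict[str, float]:
    """Accuracy (percent), precision, recall and F1 with activity positive.

    Degenerate denominators (no predicted or no true positives) yield 0 by
    convention rather than an error.
    """
    conf = np.asarray(conf)
    if conf.shape != (2, 2):
        raise ValidationError("confusion matrix must be 2x2")
    total = conf.sum()
    if total <= 0:
        raise ValidationError("confusion matrix is empty")
    tp, fn = conf[0, 0], conf[0, 1]
    fp, tn = conf[1, 0], conf[1, 1]
    accuracy = 100.0 * (tp + tn) / total
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {"accuracy": float(accuracy), "precision": float(precision),
            "recall": float(recall), "f1": float(f1)}


def compare_methods(accuracies: pd.DataFrame, proposed: str | None = None,
                    alpha: float = 0.05, n_comparisons: int | None = None,
                    test: str = "ttest") -> pd.DataFrame:
    """Paired significance tests of one method against the others.

    ``accuracies`` is subjects x methods.  Each comparison is a paired
    two-sided test across subjects; significance is declared at
    ``alpha / n_comparisons``.  Columns with identical values (zero paired
    variance) are reported as p = 1, i.e. non-significant.
    """
    if accuracies.isna().any().any():
        raise ValidationError("accuracy table has missing cells")
    if len(accuracies) < 2:
        raise ValidationError("need at least 2 subjects for a paired test")
    methods = list(accuracies.columns)
    proposed = proposed or methods[0]
    others = [m for m in methods if m != proposed]
    if n_comparisons is None:
        n_comparisons = len(others)
    threshold = alpha / n_comparisons
    rows = []
    for other in others:
        a = accuracies[proposed].to_numpy(float)
        b = accuracies[other].to_numpy(float)
        diff = a - b
        if np.allclose(diff, diff[0]) and np.isclose(diff.std(), 0):
            if np.allclose(diff, 0):
                stat, p = 0.0, 1.0
            else:
                # constant non-zero difference: zero variance, test degenerate
                stat, p = np.inf * np.sign(diff[0]), 0.0
        elif test == "ttest":
            stat, p = stats.ttest_rel(a, b)
        elif test == "wilcoxon":
            stat, p = stats.wilcoxon(a, b)
        else:
            raise ValidationError(f"unknown test {test!r}; expected ttest or wilcoxon")
        if not np.isfinite(p):
            p = 1.0
        rows.append({
            "proposed": proposed, "versus": other, "statistic": float(stat),
            "p_value": float(p), "alpha": alpha, "n_comparisons": n_comparisons,
            "corrected_threshold": threshold, "significant": bool(p < threshold),
        })
    return pd.DataFrame(rows)


def aggregate(accuracies) -> tuple[float, float, str]:
    """Mean and sample (n-1) standard deviation, plus a '90.11 ± 3.65' string."""
    a = np.asarray(accuracies, dtype=float)
    if a.size == 0:
        raise ValidationError("cannot aggregate an empty vector")
    mean = float(a.mean())
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    return mean, sd, f"{mean:.2f} ± {sd:.2f}"


def reference_subject_accuracies() -> pd.DataFrame:
    """Subject-wise accuracies (%) reported for the original 20-participant
    hand-gripping study, one column per method.

    Shipped as package data so aggregate and comparison plumbing can be
    exercised against published numbers without the private recordings.
    """
    path = resources.files("nirstack") / "data" / "reference_subject_accuracies.csv"
    with path.open() as fh:
        return pd.read_csv(fh, index_col=0)


@dataclass
class EvaluationReport:
    """Per-subject metrics plus aggregates for one method."""

    method: str
    subjects: list[dict] = field(default_factory=list)

    def add_subject(self, subject_id: str, y_true, y_pred,
                    histories: dict | None = None) -> dict:
        conf = confusion(y_true, y_pred)
        entry = {
            "subject_id": subject_id,
            "confusion": conf.tolist(),
            **scores(conf),
        }
        if histories:
            entry["histories"] = histories
        self.subjects.append(entry)
        return entry

    def accuracies(self) -> np.ndarray:
        return np.array([s["accuracy"] for s in self.subjects])

    def to_dict(self) -> dict:
        mean, sd, pretty = aggregate(self.accuracies())
        return {
            "method": self.method,
            "subjects": self.subjects,
            "aggregate": {"mean_accuracy": round(mean, 2),
                          "sd_accuracy": round(sd, 2),
                          "pretty": pretty},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        rep = cls(method=d["method"])
        rep.subjects = list(d["subjects"])
        return rep

    def accuracy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": [s["subject_id"] for s in self.subjects],
             "accuracy": [s["accuracy"] for s in self.subjects],
             "f1": [s["f1"] for s in self.subjects]}
        ).set_index("subject_id")
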