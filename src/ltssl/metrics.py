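"""Classification metrics for imbalanced single- and multi-label tasks.

Per-class one-vs-rest AUC, sensitivity, specificity, accuracy, F1 and
precision, plus their unweighted (macro) means — the macro convention is
deliberate: with a long-tailed test distribution, frequency-weighted
averages are dominated by head classes and hide tail behavior.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "metrics_from_counts",
    "auc_per_class",
    "compute_metrics",
    "evaluate_probs",
]

METRIC_NAMES = ["auc", "sensitivity", "specificity", "accuracy", "f1", "precision"]


@dataclass
class MetricsReport:
    """Per-class metric table plus macro (unweighted mean) aggregates."""

    per_class: pd.DataFrame  # one row per class, columns METRIC_NAMES
    macro: dict[str, float]
    n_samples: int
    label_mode: str

    def to_json(self) -> str:
        return json.dumps({
            "per_class": self.per_class.to_dict(orient="list"),
            "macro": self.macro,
            "n_samples": self.n_samples,
            "label_mode": self.label_mode,
        })

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        obj = json.loads(text)
        return cls(per_class=pd.DataFrame(obj["per_class"]),
                   macro=obj["macro"], n_samples=obj["n_samples"],
                   label_mode=obj["label_mode"])

    def to_csv(self, path: str) -> None:
        self.per_class.to_csv(path, index_label="class")


def confusion_counts(scores: np.ndarray, labels: np.ndarray,
                     label_mode: str = "single",
                     threshold: float = 0.5) -> pd.DataFrame:
    """Per-class one-vs-rest TP/FP/TN/FN.

    Single-label: the predicted class is the argmax of each score row.
    Multi-label: each class is predicted positive above ``threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have identical shape")
    if scores.size == 0:
        raise ValueError("empty evaluation set")
    n, C = scores.shape
    if label_mode == "single":
        pred = np.zeros_like(labels)
        pred[np.arange(n), scores.argmax(axis=1)] = 1
    else:
        pred = (scores > threshold).astype(int)
    tp = ((pred == 1) & (labels == 1)).sum(axis=0)
    fp = ((pred == 1) & (labels == 0)).sum(axis=0)
    tn = ((pred == 0) & (labels == 0)).sum(axis=0)
    fn = ((pred == 0) & (labels == 1)).sum(axis=0)
    return pd.DataFrame({"tp": tp, "fp": fp, "tn": tn, "fn": fn})


def metrics_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity, specificity, accuracy, precision and F1 from confusion
    counts; undefined ratios (zero denominators) give NaN."""
    tp, fp = counts["tp"].to_numpy(float), counts["fp"].to_numpy(float)
    tn, fn = counts["tn"].to_numpy(float), counts["fn"].to_numpy(float)

    def safe(num, den):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    sens = safe(tp, tp + fn)
    spec = safe(tn, tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    prec = safe(tp, tp + fp)
    with np.errstate(invalid="ignore"):
        f1 = np.where((prec + sens) > 0, 2 * prec * sens / (prec + sens), 0.0)
    return pd.DataFrame({"sensitivity": sens, "specificity": spec,
                         "accuracy": acc, "f1": f1, "precision": prec})


def auc_per_class(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-vs-rest rank AUC (midrank tie handling) per class.

    A class whose test column contains a single label value has no defined
    AUC; it is reported as NaN with a warning and excluded from macro means.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    out = np.full(labels.shape[1], np.nan)
    for c in range(labels.shape[1]):
        y = labels[:, c]
        if y.min() == y.max():
            warnings.warn(f"class {c} has a single label value; AUC undefined")
            continue
        out[c] = roc_auc_score(y, scores[:, c])
    return out


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    label_mode: str = "single") -> MetricsReport:
    """Full per-class + macro metric report from scores and binary labels."""
    counts = confusion_counts(scores, labels, label_mode)
    table = metrics_from_counts(counts)
    table.insert(0, "auc", auc_per_class(scores, labels))
    macro = {}
    for name in METRIC_NAMES:
        vals = table[name].to_numpy(float)
        macro[name] = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
    return MetricsReport(per_class=table, macro=macro,
                         n_samples=labels.shape[0], label_mode=label_mode)


def evaluate_probs(predict_fn, X: np.ndarray, Y: np.ndarray,
                   label_mode: str = "single") -> MetricsReport:
    """Evaluate a ``predict_fn(X) -> probability matrix`` on a test set."""
    return compute_metrics(predict_fn(X), Y, label_mode)
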