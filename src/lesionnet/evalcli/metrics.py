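"""Classification metrics: confusion matrix, per-class scores, OvR AUC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class MetricsReport:
    accuracy: float
    confusion: np.ndarray                 # C x C counts, rows = true class
    per_class: Dict[int, Dict[str, float]]
    weighted: Dict[str, float]
    auc_per_class: Dict[int, Optional[float]]
    macro_auc: Optional[float]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "weighted": self.weighted,
            "auc_per_class": {str(k): v for k, v in self.auc_per_class.items()},
            "macro_auc": self.macro_auc,
        }


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
                     ) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def evaluate(predicted_probs: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Argmax predictions (ties -> lowest class index) scored per class.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean,
    specificity = TN/(TN+FP); one-vs-rest AUC from the probability columns;
    weighted averages by class support.  A class with no true samples gets
    undefined (None/NaN) metrics and is excluded from the weighted averages.
    """
    probs = np.asarray(predicted_probs, dtype=np.float64)
    labels = np.asarray(labels)
    if len(probs) != len(labels):
        raise ValueError("probs/labels length mismatch")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    n_classes = probs.shape[1]
    preds = probs.argmax(axis=1)
    cm = confusion_matrix(labels, preds, n_classes)
    total = cm.sum()

    per_class: Dict[int, Dict[str, float]] = {}
    aucs: Dict[int, Optional[float]] = {}
    for c in range(n_classes):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        support = int(tp + fn)
        if support == 0:
            warnings.warn(f"class {c} absent from labels; metrics undefined",
                          stacklevel=2)
            per_class[c] = {"precision": np.nan, "recall": np.nan,
                            "f1": np.nan, "specificity": np.nan, "support": 0}
            aucs[c] = None
            continue
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn)
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        specificity = tn / (tn + fp) if tn + fp else 0.0
        per_class[c] = {"precision": float(precision), "recall": float(recall),
                        "f1": float(f1), "specificity": float(specificity),
                        "support": support}
        binary = (labels == c).astype(int)
        aucs[c] = (float(roc_auc_score(binary, probs[:, c]))
                   if 0 < binary.sum() < len(binary) else None)

    defined = [c for c in range(n_classes) if per_class[c]["support"] > 0]
    supports = np.array([per_class[c]["support"] for c in defined], dtype=float)
    weighted = {
        key: float(sum(per_class[c][key] * per_class[c]["support"]
                       for c in defined) / supports.sum())
        for key in ("precision", "recall", "f1", "specificity")
    }
    auc_vals = [aucs[c] for c in defined if aucs[c] is not None]
    macro_auc = float(np.mean(auc_vals)) if auc_vals else None

    return MetricsReport(
        accuracy=float(np.trace(cm) / total),
        confusion=cm,
        per_class=per_class,
        weighted=weighted,
        auc_per_class=aucs,
        macro_auc=macro_auc,
    )
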