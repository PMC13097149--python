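"""Selective prediction: rejection curves and threshold selection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class RejectionCurve:
    thresholds: np.ndarray
    reject_pct: np.ndarray
    accepted_accuracy_pct: np.ndarray      # NaN where everything is rejected
    incorrect_rejected_pct: np.ndarray
    correct_rejected_pct: np.ndarray

    def validate(self) -> "RejectionCurve":
        for arr in (self.reject_pct, self.incorrect_rejected_pct,
                    self.correct_rejected_pct):
            if ((arr < 0) | (arr > 100)).any():
                raise ValueError("percentages must be in [0, 100]")
        if (np.diff(self.reject_pct) > 1e-9).any():
            raise ValueError("reject fraction must be non-increasing in the threshold")
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "reject_pct": self.reject_pct,
            "accepted_accuracy_pct": self.accepted_accuracy_pct,
            "incorrect_rejected_pct": self.incorrect_rejected_pct,
            "correct_rejected_pct": self.correct_rejected_pct,
        })


def rejection_analysis(scores: Sequence[float], correct: Sequence[bool],
                       thresholds: Sequence[float]) -> RejectionCurve:
    """Evaluate the reject-if-score-exceeds-threshold rule at each threshold.

    Rejection uses strict inequality (score > threshold).  With all samples
    rejected the accepted accuracy is undefined and reported as NaN.
    """
    scores = np.asarray(scores, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if scores.shape != correct.shape:
        raise ValueError("scores/correct length mismatch")
    if (np.diff(thresholds) < 0).any():
        raise ValueError("thresholds must be sorted ascending")
    n = len(scores)
    n_cor = int(correct.sum())
    n_inc = n - n_cor

    rej_pct, acc_pct, inc_rej, cor_rej = [], [], [], []
    for t in thresholds:
        rejected = scores > t
        kept = ~rejected
        rej_pct.append(100.0 * rejected.mean())
        if kept.any():
            acc_pct.append(100.0 * correct[kept].mean())
        else:
            warnings.warn(f"all samples rejected at threshold {t}; accepted "
                          "accuracy undefined", stacklevel=2)
            acc_pct.append(np.nan)
        inc_rej.append(100.0 * (rejected & ~correct).sum() / n_inc if n_inc else 0.0)
        cor_rej.append(100.0 * (rejected & correct).sum() / n_cor if n_cor else 0.0)

    return RejectionCurve(
        thresholds=thresholds,
        reject_pct=np.asarray(rej_pct),
        accepted_accuracy_pct=np.asarray(acc_pct),
        incorrect_rejected_pct=np.asarray(inc_rej),
        correct_rejected_pct=np.asarray(cor_rej),
    ).validate()


def select_threshold(scores: Sequence[float], correct: Sequence[bool],
                     max_correct_rejection: float = 0.05) -> float:
    """Pick the threshold maximizing accepted accuracy subject to rejecting
    at most ``max_correct_rejection`` of the correct predictions.

    Candidates are the unique score values; ties prefer the largest
    threshold (least rejection).  An infeasible constraint falls back to the
    maximum score (reject nothing) with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty validation arrays")
    n_cor = int(correct.sum())
    candidates = np.unique(scores)
    best_t: Optional[float] = None
    best_acc = -1.0
    for t in candidates[::-1]:                 # descending: ties keep larger t
        kept = scores <= t
        cor_rej = ((~kept) & correct).sum() / n_cor if n_cor else 0.0
        if cor_rej > max_correct_rejection or not kept.any():
            continue
        acc = correct[kept].mean()
        if acc > best_acc:
            best_acc, best_t = acc, float(t)
    if best_t is None:
        warnings.warn("no threshold satisfies the correct-rejection "
                      "constraint; rejecting nothing", stacklevel=2)
        return float(scores.max())
    return best_t
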