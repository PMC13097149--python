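"""Confidence calibration: reliability bins, ECE, multi-class Brier score."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class CalibrationReport:
    bin_edges: np.ndarray        # n_bins + 1 equal-width edges on [0, 1]
    bin_confidence: np.ndarray   # NaN for empty bins
    bin_accuracy: np.ndarray
    bin_weight: np.ndarray       # fraction of samples per bin (sums to 1)
    ece: float
    brier: float

    def validate(self) -> "CalibrationReport":
        if not 0.0 <= self.ece <= 1.0:
            raise ValueError("ECE must be in [0, 1]")
        if not np.isclose(self.bin_weight.sum(), 1.0):
            raise ValueError("bin weights must sum to 1")
        return self

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "bin_confidence": self.bin_confidence.tolist(),
            "bin_accuracy": self.bin_accuracy.tolist(),
            "bin_weight": self.bin_weight.tolist(),
            "ece": self.ece,
            "brier": self.brier,
        }


def brier_score(probs: np.ndarray, labels: np.ndarray) -> float:
    """Multi-class Brier: mean squared error between the probability vector
    and the one-hot label."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    onehot = np.eye(probs.shape[1])[labels]
    return float(((probs - onehot) ** 2).sum(axis=1).mean())


def calibration_report(confidences: Sequence[float], correct: Sequence[bool],
                       n_bins: int = 10,
                       probs: Optional[np.ndarray] = None,
                       labels: Optional[np.ndarray] = None) -> CalibrationReport:
    """Equal-width reliability bins on [0,1]; ECE is the bin-weighted mean
    absolute confidence/accuracy gap.  The Brier score uses the full
    probability vectors when given, else the binary (confidence, correct)
    reduction."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    conf = np.asarray(confidences, dtype=np.float64)
    corr = np.asarray(correct, dtype=bool)
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError("confidences must be in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins; confidence 0 lands in the first bin
    idx = np.clip(np.ceil(conf * n_bins).astype(int) - 1, 0, n_bins - 1)

    bin_conf = np.full(n_bins, np.nan)
    bin_acc = np.full(n_bins, np.nan)
    bin_w = np.zeros(n_bins)
    ece = 0.0
    n = len(conf)
    for b in range(n_bins):
        in_bin = idx == b
        if not in_bin.any():
            continue
        bin_w[b] = in_bin.sum() / n
        bin_conf[b] = conf[in_bin].mean()
        bin_acc[b] = corr[in_bin].mean()
        ece += bin_w[b] * abs(bin_acc[b] - bin_conf[b])

    if probs is not None and labels is not None:
        brier = brier_score(probs, labels)
    else:
        brier = float(((conf - corr.astype(float)) ** 2).mean())

    return CalibrationReport(bin_edges=edges, bin_confidence=bin_conf,
                             bin_accuracy=bin_acc, bin_weight=bin_w,
                             ece=float(ece), brier=brier).validate()
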