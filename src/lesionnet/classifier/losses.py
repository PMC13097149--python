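"""Classification-side losses and the composite training objective."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from ..nn import Tensor

LOG_FLOOR = 1e-12


@dataclass
class ClassProbabilities:
    probs: np.ndarray          # length-C simplex vector
    logits: np.ndarray         # length-C pre-softmax scores
    embedding: np.ndarray      # pooled+projected feature vector
    label: int = -1            # argmax prediction

    def validate(self) -> "ClassProbabilities":
        if (self.probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")
        return self


@dataclass
class LossBreakdown:
    l_seg: float
    l_cls: float
    l_att: float
    l_unc: float
    lambdas: Tuple[float, float, float, float]
    l_total: float = 0.0

    def __post_init__(self):
        l1, l2, l3, l4 = self.lambdas
        self.l_total = (l1 * self.l_seg + l2 * self.l_cls
                        + l3 * self.l_att + l4 * self.l_unc)


def cross_entropy(probs: np.ndarray, y: int) -> float:
    """-log p_y with the probability clamped at 1e-12."""
    probs = np.asarray(probs, dtype=np.float64)
    if not 0 <= y < probs.shape[-1]:
        raise ValueError("label out of range")
    return float(-np.log(max(probs[y], LOG_FLOOR)))


def cross_entropy_t(log_probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood from (N,C) log-probabilities."""
    n, c = log_probs.shape
    onehot = Tensor(np.eye(c, dtype=np.float32)[labels])
    return -(log_probs * onehot).sum() * (1.0 / n)


def attention_alignment_loss(a: np.ndarray, m: np.ndarray) -> float:
    """L_att = 1 - sum(A.M)/sum(A); invariant to positive rescaling of A."""
    a = np.asarray(a, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    if a.shape != m.shape:
        raise ValueError("attention map and mask dims must match")
    if (a < 0).any():
        raise ValueError("attention map must be nonnegative")
    total = a.sum()
    if total == 0:
        warnings.warn("attention map has zero mass; alignment loss "
                      "degenerates to 0", stacklevel=2)
        return 0.0
    return float(1.0 - (a * m).sum() / total)


def attention_alignment_loss_t(a: Tensor, m: Tensor, eps: float = 1e-8) -> Tensor:
    """Batch tensor version; a, m: (N,1,H,W); mean over samples."""
    num = (a * m).sum(axis=(1, 2, 3))
    den = a.sum(axis=(1, 2, 3))
    return (1.0 - num / (den + eps)).mean()


def confidence_penalty(probs: np.ndarray) -> float:
    """L_unc = 1 - H(p)/ln C: penalizes overconfident (low-entropy) outputs.

    The published objective names an uncertainty-calibration term but never
    defines it; this normalized confidence penalty is the documented stand-in
    (nonnegative, 0 at uniform, 1 at one-hot).
    """
    p = np.clip(np.asarray(probs, dtype=np.float64), LOG_FLOOR, 1.0)
    c = p.shape[-1]
    h = -(p * np.log(p)).sum(axis=-1)
    return float(np.mean(1.0 - h / np.log(c)))


def confidence_penalty_t(probs: Tensor, log_probs: Tensor) -> Tensor:
    n, c = probs.shape
    h = -(probs * log_probs).sum(axis=1)
    return (1.0 - h * (1.0 / np.log(c))).mean()


def total_loss(l_seg: float, l_cls: float, l_att: float, l_unc: float,
               lambdas: Sequence[float]) -> LossBreakdown:
    """Weighted combination of the four objective components."""
    lambdas = tuple(float(l) for l in lambdas)
    if len(lambdas) != 4:
        raise ValueError("expected 4 lambda weights")
    if any(l < 0 for l in lambdas):
        raise ValueError("lambda weights must be nonnegative")
    for name, v in (("l_seg", l_seg), ("l_cls", l_cls),
                    ("l_att", l_att), ("l_unc", l_unc)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    return LossBreakdown(l_seg=float(l_seg), l_cls=float(l_cls),
                         l_att=float(l_att), l_unc=float(l_unc),
                         lambdas=lambdas)
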