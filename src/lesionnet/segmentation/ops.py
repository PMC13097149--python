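"""Mask algebra: Dice loss, background suppression, binarization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Tensor

DICE_EPS = 1e-6


@dataclass
class SoftMask:
    """Predicted per-pixel lesion probability map."""

    values: np.ndarray  # H x W in [0, 1]

    def validate(self) -> "SoftMask":
        if self.values.ndim != 2:
            raise ValueError("SoftMask must be 2-D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("SoftMask values must lie in [0, 1]")
        return self


@dataclass
class MaskedImage:
    """Background-suppressed normalized image."""

    values: np.ndarray  # H x W x 3


def dice_loss(m: np.ndarray, g: np.ndarray, eps: float = DICE_EPS) -> float:
    """1 - 2|M.G| / (|M| + |G|), smoothed by ``eps`` in numerator and
    denominator.  Both-empty inputs return 0 by the eps-convention (an empty
    prediction of an empty mask is treated as correct)."""
    m = np.asarray(m, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if m.shape != g.shape:
        raise ValueError("mask shape mismatch")
    inter = (m * g).sum()
    return float(1.0 - (2.0 * inter + eps) / (m.sum() + g.sum() + eps))


def dice_coefficient(m: np.ndarray, g: np.ndarray, eps: float = DICE_EPS) -> float:
    return 1.0 - dice_loss(m, g, eps)


def dice_loss_t(m: Tensor, g: Tensor, eps: float = DICE_EPS) -> Tensor:
    """Differentiable batch Dice loss: mean over samples of Eq.-style
    per-sample soft Dice.  ``m``, ``g``: (N, 1, H, W)."""
    inter = (m * g).sum(axis=(1, 2, 3))
    denom = m.sum(axis=(1, 2, 3)) + g.sum(axis=(1, 2, 3))
    return (1.0 - (2.0 * inter + eps) / (denom + eps)).mean()


def apply_mask(image: np.ndarray, m: np.ndarray,
               background_attenuation: float = 0.0) -> np.ndarray:
    """x_m = x' * (M + a*(1-M)); a=0 is the literal elementwise product."""
    if not 0.0 <= background_attenuation <= 1.0:
        raise ValueError("background_attenuation must be in [0, 1]")
    if m.shape != image.shape[:2]:
        raise ValueError("mask spatial dims must match image")
    gate = m + background_attenuation * (1.0 - m)
    return (image * gate[..., None]).astype(np.float32)


def apply_mask_t(image: Tensor, m: Tensor, background_attenuation: float = 0.0) -> Tensor:
    """Tensor version; image (N,3,H,W), m (N,1,H,W)."""
    gate = m * (1.0 - background_attenuation) + background_attenuation
    return image * gate


def binarize_mask(m: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Pixelwise threshold; ties (value == t) go to foreground."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return (np.asarray(m) >= t).astype(np.uint8)
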