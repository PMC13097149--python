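"""Gradient-based attribution: Grad-CAM on the attention-refined features
and pixel-level saliency on the input."""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..nn import Tensor
from ..nn.functional import bilinear_resize
from ..segmentation.ops import apply_mask_t
from ..classifier.model import LesionPipeline


def _max_normalize(m: np.ndarray) -> np.ndarray:
    peak = m.max()
    return m / peak if peak > 0 else m  # all-zero maps stay zero


def grad_cam(pipe: LesionPipeline, image: np.ndarray,
             target_class: Optional[int] = None) -> np.ndarray:
    """Class-activation map at input resolution.

    Channel weights are the spatial means of d(logit_target)/dF over the
    refined feature map F = f_a; the map is ReLU(sum_k alpha_k F_k),
    bilinearly upsampled and max-normalized.
    """
    x = pipe.prepare([image])
    masks = pipe.predict_soft_masks(x)
    xt = Tensor(x, requires_grad=True)
    x_m = apply_mask_t(xt, Tensor(masks), pipe.config.background_attenuation)
    pipe.classifier.eval()
    out = pipe.classifier(x_m)
    logits = out["logits"]
    if target_class is None:
        target_class = int(logits.data[0].argmax())
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError("target_class out of range")

    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    f_a = out["f_a"]
    logits.backward(onehot)

    alpha = f_a.grad[0].mean(axis=(1, 2))               # (C,)
    cam = np.maximum((alpha[:, None, None] * f_a.data[0]).sum(axis=0), 0.0)
    cam = bilinear_resize(cam, x.shape[2:])
    return _max_normalize(cam).astype(np.float32)


def grad_cam_from_arrays(features: np.ndarray, grads: np.ndarray,
                         out_hw: Optional[tuple] = None) -> np.ndarray:
    """Grad-CAM core on explicit feature/gradient arrays (C,h,w) — the form
    checked against the hand-computed oracle."""
    alpha = grads.mean(axis=(1, 2))
    cam = np.maximum((alpha[:, None, None] * features).sum(axis=0), 0.0)
    if out_hw is not None:
        cam = bilinear_resize(cam, out_hw)
    return _max_normalize(cam).astype(np.float32)


def saliency(pipe: LesionPipeline, image: np.ndarray,
             target_class: Optional[int] = None) -> np.ndarray:
    """Max-over-channels |d logit_top / d input|, max-normalized."""
    x = pipe.prepare([image])
    masks = pipe.predict_soft_masks(x)
    xt = Tensor(x, requires_grad=True)
    x_m = apply_mask_t(xt, Tensor(masks), pipe.config.background_attenuation)
    pipe.classifier.eval()
    out = pipe.classifier(x_m)
    logits = out["logits"]
    if target_class is None:
        target_class = int(logits.data[0].argmax())
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    logits.backward(onehot)
    sal = np.abs(xt.grad[0]).max(axis=0)
    return _max_normalize(sal).astype(np.float32)
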