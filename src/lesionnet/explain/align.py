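"""Mask-aligned explanations and the attribution-coverage metric."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ExplanationMap:
    raw_map: np.ndarray        # H x W, max-normalized nonnegative
    aligned_map: np.ndarray    # raw_map * M
    target_class: int
    method: str                # "gradcam" | "saliency"

    def validate(self) -> "ExplanationMap":
        if self.method not in ("gradcam", "saliency"):
            raise ValueError("method must be 'gradcam' or 'saliency'")
        if self.raw_map.min() < 0 or self.raw_map.max() > 1:
            raise ValueError("raw_map must be max-normalized to [0, 1]")
        return self


def align_explanation(m_exp: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Elementwise product of the explanation with the segmentation mask."""
    if m_exp.shape != m.shape:
        raise ValueError("explanation/mask dims must match")
    return (m_exp * m).astype(np.float32)


def explanation_coverage(map_: np.ndarray, reference_mask: np.ndarray) -> float:
    """Fraction of attribution mass falling inside the reference mask."""
    map_ = np.asarray(map_, dtype=np.float64)
    mask = np.asarray(reference_mask, dtype=np.float64)
    if map_.shape != mask.shape:
        raise ValueError("map/mask dims must match")
    if (map_ < 0).any():
        raise ValueError("map must be nonnegative")
    total = map_.sum()
    if total == 0:
        raise ValueError("zero-mass map: coverage undefined")
    return float((map_ * mask).sum() / total)
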