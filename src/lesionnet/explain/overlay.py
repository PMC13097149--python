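"""Heatmap overlays for qualitative inspection."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib import colormaps

from ..data.io import save_image


def render_overlay(image: np.ndarray, map_: np.ndarray, out_path: Path,
                   alpha: float = 0.45, cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a normalized heatmap onto an RGB image and save as PNG."""
    if map_.shape != image.shape[:2]:
        raise ValueError("map dims must match image spatial dims")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    heat = colormaps[cmap](np.clip(map_, 0.0, 1.0))[..., :3]
    blended = (1.0 - alpha) * image + alpha * heat
    blended = np.clip(blended, 0.0, 1.0).astype(np.float32)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    save_image(blended if alpha > 0 else image, out_path)
    return blended
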