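"""PNG / CSV dataset persistence.

Mask dialect: 8-bit grayscale PNG, 255 = lesion, 0 = background; the
loader thresholds at 128.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
from PIL import Image

from .specs import ImageSample

MASK_THRESHOLD = 128


def save_image(image: np.ndarray, path: Path) -> None:
    arr = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32)
    return arr / 255.0


def save_mask(mask: np.ndarray, path: Path) -> None:
    arr = (mask.astype(np.uint8) * 255)
    Image.fromarray(arr, mode="L").save(path)


def load_mask(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr >= MASK_THRESHOLD).astype(np.uint8)


def load_dataset(root: Path) -> List[ImageSample]:
    """Read a dataset written by :func:`generate_dataset` (or hand-assembled
    in the same layout) back into memory."""
    root = Path(root)
    meta = pd.read_csv(root / "metadata.csv")
    samples = []
    for _, row in meta.iterrows():
        img = load_image(root / row["image_path"])
        mask = (
            load_mask(root / row["mask_path"])
            if isinstance(row.get("mask_path"), str) and row["mask_path"]
            else np.zeros(img.shape[:2], dtype=np.uint8)
        )
        samples.append(
            ImageSample(image=img, mask=mask, label=int(row["label"]),
                        sample_id=str(row["sample_id"])).validate()
        )
    return samples
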