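"""Augmentation and input standardization."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .specs import AugmentationParams, ImageSample, NormalizationStats


def _apply_geometric(image: np.ndarray, mask: np.ndarray,
                     hflip: bool, vflip: bool, angle_deg: float
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Identical geometric transform on image and mask; mask re-binarized."""
    if hflip:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if vflip:
        image, mask = image[::-1], mask[::-1]
    if angle_deg != 0.0:
        image = ndimage.rotate(image, angle_deg, axes=(1, 0), reshape=False,
                               order=1, mode="nearest")
        mask = ndimage.rotate(mask.astype(np.uint8), angle_deg, axes=(1, 0),
                              reshape=False, order=0, mode="constant", cval=0)
    return (np.ascontiguousarray(np.clip(image, 0.0, 1.0), dtype=np.float32),
            np.ascontiguousarray(mask > 0).astype(np.uint8))


def augment(sample: ImageSample, params: AugmentationParams, seed: int) -> ImageSample:
    """Random flips/rotation (shared by image and mask) plus photometric
    jitter on the image only.  All-zero params are an exact identity."""
    params.validate()
    rng = np.random.default_rng(seed)
    hflip = params.p_hflip > 0 and rng.random() < params.p_hflip
    vflip = params.p_vflip > 0 and rng.random() < params.p_vflip
    angle = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg) \
        if params.max_rotation_deg > 0 else 0.0

    image, mask = _apply_geometric(sample.image, sample.mask, hflip, vflip, angle)

    if params.brightness_delta > 0:
        image = image + params.brightness_delta * rng.uniform(-1, 1)
    if params.contrast_delta > 0:
        m = image.mean()
        image = m + (image - m) * (1.0 + params.contrast_delta * rng.uniform(-1, 1))
    if params.color_jitter_delta > 0:
        image = image * (1.0 + params.color_jitter_delta * rng.uniform(-1, 1, 3))
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return ImageSample(image=image, mask=mask, label=sample.label,
                       sample_id=sample.sample_id).validate()


def resize_image(image: np.ndarray, out_size: int) -> np.ndarray:
    if image.shape[0] == out_size and image.shape[1] == out_size:
        return image.astype(np.float32)
    out = _sk_resize(image, (out_size, out_size), order=1, mode="edge",
                     anti_aliasing=image.shape[0] > out_size, preserve_range=True)
    return out.astype(np.float32)


def resize_mask(mask: np.ndarray, out_size: int) -> np.ndarray:
    """Nearest-neighbour resize keeping the mask strictly binary."""
    if mask.shape[0] == out_size and mask.shape[1] == out_size:
        return mask.astype(np.uint8)
    out = _sk_resize(mask.astype(np.float32), (out_size, out_size), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def normalize(image: np.ndarray, stats: Optional[NormalizationStats] = None,
              out_size: Optional[int] = None) -> np.ndarray:
    """x' = (x - mean) / std per channel, after optional bilinear resize to
    the working resolution."""
    stats = (stats or NormalizationStats()).validate()
    if image.shape[-1] != len(stats.mean):
        raise ValueError("channel count does not match normalization stats")
    if out_size is not None:
        image = resize_image(image, out_size)
    mean = np.asarray(stats.mean, dtype=np.float32)
    std = np.asarray(stats.std, dtype=np.float32)
    return ((image - mean) / std).astype(np.float32)


def denormalize(image: np.ndarray, stats: Optional[NormalizationStats] = None
                ) -> np.ndarray:
    stats = (stats or NormalizationStats()).validate()
    mean = np.asarray(stats.mean, dtype=np.float32)
    std = np.asarray(stats.std, dtype=np.float32)
    return np.clip(image * std + mean, 0.0, 1.0)
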