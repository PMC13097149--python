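"""Parameter records for synthetic sample generation and preprocessing."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

#: Channel-wise ImageNet statistics used for input standardization.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

#: Default working resolution (desk scale; full scale would be 224).
DEFAULT_RESOLUTION = 64

_SKIN_TONE = (0.80, 0.62, 0.52)


@dataclass
class LesionSpec:
    """Morphology and artifact parameters for one lesion class.

    ``base_radius_frac = 0`` disables the lesion entirely (background-only
    sample, useful as an out-of-distribution probe).
    """

    class_id: int
    base_radius_frac: float = 0.25
    asymmetry: float = 0.0
    border_irregularity: float = 0.0
    n_boundary_harmonics: int = 4
    color_palette: List[Tuple[float, float, float]] = field(
        default_factory=lambda: [(0.45, 0.30, 0.22)]
    )
    heterogeneity: float = 0.0
    hair_count: int = 0
    illumination_gradient: float = 0.0
    noise_sigma: float = 0.0

    def validate(self) -> "LesionSpec":
        if not 0.0 <= self.base_radius_frac < 0.5:
            raise ValueError("base_radius_frac must be in [0, 0.5)")
        for name in ("asymmetry", "border_irregularity", "heterogeneity",
                     "illumination_gradient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_boundary_harmonics < 1:
            raise ValueError("n_boundary_harmonics must be >= 1")
        if self.hair_count < 0 or self.noise_sigma < 0:
            raise ValueError("hair_count and noise_sigma must be nonnegative")
        if self.base_radius_frac > 0 and not self.color_palette:
            raise ValueError("color_palette must be nonempty for a visible lesion")
        return self

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["color_palette"] = [list(c) for c in self.color_palette]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LesionSpec":
        d = dict(d)
        d["color_palette"] = [tuple(c) for c in d.get("color_palette", [])]
        return cls(**d).validate()


@dataclass
class ImageSample:
    """An image with its ground-truth lesion mask and class label."""

    image: np.ndarray          # H x W x 3, floats in [0, 1]
    mask: np.ndarray           # H x W, {0, 1}
    label: int
    sample_id: str = ""

    def validate(self) -> "ImageSample":
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be HxWx3")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask dims must equal image spatial dims")
        if not np.isfinite(self.image).all():
            raise ValueError("image must be finite")
        u = np.unique(self.mask)
        if not np.isin(u, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
        return self


@dataclass
class NormalizationStats:
    mean: Tuple[float, ...] = IMAGENET_MEAN
    std: Tuple[float, ...] = IMAGENET_STD

    def validate(self) -> "NormalizationStats":
        if len(self.mean) != len(self.std):
            raise ValueError("mean/std length mismatch")
        if any(s <= 0 for s in self.std):
            raise ValueError("std must be positive elementwise")
        return self


@dataclass
class AugmentationParams:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    max_rotation_deg: float = 20.0
    brightness_delta: float = 0.1
    contrast_delta: float = 0.1
    color_jitter_delta: float = 0.05

    def validate(self) -> "AugmentationParams":
        if not (0.0 <= self.p_hflip <= 1.0 and 0.0 <= self.p_vflip <= 1.0):
            raise ValueError("flip probabilities must be in [0, 1]")
        for name in ("max_rotation_deg", "brightness_delta", "contrast_delta",
                     "color_jitter_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        return self


def default_class_specs(n_classes: int = 3) -> List[LesionSpec]:
    """Morphology profiles that differ in border irregularity, asymmetry,
    pigment heterogeneity and palette — loosely mimicking the spread of
    dermoscopic appearance across diagnostic categories."""
    palettes = [
        [(0.48, 0.32, 0.24), (0.55, 0.38, 0.28)],                      # tan, regular
        [(0.30, 0.16, 0.12), (0.14, 0.09, 0.08), (0.50, 0.28, 0.20)],  # dark, chaotic
        [(0.52, 0.29, 0.18), (0.64, 0.36, 0.21)],                      # near class 0
        [(0.40, 0.28, 0.30), (0.25, 0.18, 0.22)],
        [(0.55, 0.42, 0.30), (0.35, 0.30, 0.22)],
    ]
    # classes 0 and 2 overlap in colour and differ mainly in border
    # irregularity/heterogeneity, keeping a few honest confusions
    profiles = [
        dict(base_radius_frac=0.24, asymmetry=0.10, border_irregularity=0.05,
             heterogeneity=0.15),
        dict(base_radius_frac=0.30, asymmetry=0.55, border_irregularity=0.40,
             heterogeneity=0.80),
        dict(base_radius_frac=0.22, asymmetry=0.30, border_irregularity=0.22,
             heterogeneity=0.45),
        dict(base_radius_frac=0.27, asymmetry=0.40, border_irregularity=0.25,
             heterogeneity=0.55),
        dict(base_radius_frac=0.19, asymmetry=0.15, border_irregularity=0.32,
             heterogeneity=0.25),
    ]
    if n_classes > len(profiles):
        raise ValueError(f"at most {len(profiles)} built-in class profiles")
    return [
        LesionSpec(class_id=i, color_palette=palettes[i],
                   hair_count=3, illumination_gradient=0.2, noise_sigma=0.03,
                   **profiles[i]).validate()
        for i in range(n_classes)
    ]
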