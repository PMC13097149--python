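"""Synthetic dermoscopy-style sample and dataset generation.

Lesions are radially perturbed ellipses filled with blended pigment
patches over a textured skin-tone background.  Hair strokes, an
illumination gradient and sensor noise are overlaid *after* the mask is
captured, so the ground-truth mask marks lesion support only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import save_image, save_mask
from .specs import ImageSample, LesionSpec, _SKIN_TONE


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-sample seed; adding samples never reshuffles earlier ones."""
    ss = np.random.SeedSequence((int(master_seed), int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _low_freq_field(rng: np.random.Generator, size: int, grid: int = 6) -> np.ndarray:
    """Smooth random field in roughly [-1, 1]."""
    coarse = rng.normal(size=(grid, grid))
    zoom = (size / grid, size / grid)
    f = ndimage.zoom(coarse, zoom, order=1, mode="nearest", grid_mode=True)
    return f[:size, :size]


def _lesion_mask(rng: np.random.Generator, spec: LesionSpec, size: int) -> np.ndarray:
    r0 = spec.base_radius_frac * size
    cx = size / 2 + rng.uniform(-1, 1) * 0.06 * size
    cy = size / 2 + rng.uniform(-1, 1) * 0.06 * size
    # asymmetry: unequal axes plus a centroid offset of the ellipse frame
    ax = r0 * (1.0 + 0.55 * spec.asymmetry)
    ay = r0 * (1.0 - 0.40 * spec.asymmetry)
    psi = rng.uniform(0, np.pi)

    ks = np.arange(2, 2 + spec.n_boundary_harmonics)
    amps = spec.border_irregularity * rng.uniform(0.5, 1.0, ks.size) / np.sqrt(ks)
    phases = rng.uniform(0, 2 * np.pi, ks.size)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    xr = np.cos(psi) * dx + np.sin(psi) * dy
    yr = -np.sin(psi) * dx + np.cos(psi) * dy
    u, v = xr / ax, yr / ay
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)
    rho = 1.0 + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, ks, phases))
    rho = np.clip(rho, 0.2, None)
    return (r <= rho).astype(np.uint8)


def _lesion_color(rng: np.random.Generator, spec: LesionSpec, size: int) -> np.ndarray:
    palette = np.asarray(spec.color_palette, dtype=np.float64)  # K x 3
    k = palette.shape[0]
    if k == 1 or spec.heterogeneity == 0:
        base = palette.mean(axis=0)
        color = np.broadcast_to(base, (size, size, 3)).copy()
    else:
        fields = np.stack([_low_freq_field(rng, size, grid=5) for _ in range(k)])
        logits = fields * (1.0 + 10.0 * spec.heterogeneity)
        logits -= logits.max(axis=0, keepdims=True)
        w = np.exp(logits)
        w /= w.sum(axis=0, keepdims=True)          # K x H x W patch weights
        color = np.einsum("khw,kc->hwc", w, palette)
    # mild fine-grained pigment texture
    tex = _low_freq_field(rng, size, grid=12) * 0.03 * (0.5 + spec.heterogeneity)
    return np.clip(color + tex[..., None], 0.0, 1.0)


def _draw_hair(rng: np.random.Generator, image: np.ndarray, count: int) -> np.ndarray:
    size = image.shape[0]
    alpha = np.zeros((size, size), dtype=np.float64)
    for _ in range(count):
        p = rng.uniform(0, size, (3, 2))           # quadratic Bezier control pts
        t = np.linspace(0, 1, 4 * size)[:, None]
        pts = ((1 - t) ** 2) * p[0] + 2 * (1 - t) * t * p[1] + (t ** 2) * p[2]
        ij = np.round(pts).astype(int)
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)
        alpha[ij[ok, 1], ij[ok, 0]] = 1.0
    if alpha.any():
        alpha = np.clip(ndimage.gaussian_filter(alpha, 0.6) * 1.5, 0.0, 0.85)
    hair_color = np.array([0.12, 0.10, 0.09])
    return image * (1 - alpha[..., None]) + hair_color * alpha[..., None]


def generate_sample(spec: LesionSpec, image_size: int, seed: int) -> ImageSample:
    """Deterministically render one synthetic dermoscopy-style sample."""
    spec.validate()
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    rng = np.random.default_rng(seed)

    base = np.asarray(_SKIN_TONE) + rng.uniform(-0.05, 0.05, 3)
    image = np.broadcast_to(base, (image_size, image_size, 3)).copy()
    image += _low_freq_field(rng, image_size, grid=7)[..., None] * 0.025

    if spec.base_radius_frac > 0:
        mask = _lesion_mask(rng, spec, image_size)
        color = _lesion_color(rng, spec, image_size)
        # soft edge for compositing only; the ground truth stays crisp
        alpha = ndimage.gaussian_filter(mask.astype(np.float64), 0.7)
        alpha = np.clip(alpha, 0.0, 1.0)
        image = image * (1 - alpha[..., None]) + color * alpha[..., None]
    else:
        mask = np.zeros((image_size, image_size), dtype=np.uint8)

    # artifacts after mask capture: hair, illumination gradient, noise
    if spec.hair_count > 0:
        image = _draw_hair(rng, image, spec.hair_count)
    if spec.illumination_gradient > 0:
        ang = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:image_size, 0:image_size] / (image_size - 1)
        ramp = (xx - 0.5) * np.cos(ang) + (yy - 0.5) * np.sin(ang)
        image = image * (1.0 + spec.illumination_gradient * ramp[..., None])
    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, image.shape)

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return ImageSample(image=image, mask=mask, label=spec.class_id).validate()


def boundary_roughness(mask: np.ndarray) -> float:
    """std/mean of centroid-to-boundary radii (0 for a perfect circle)."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    boundary = mask & ~ndimage.binary_erosion(mask)
    ys, xs = np.nonzero(boundary)
    cy, cx = ndimage.center_of_mass(mask)
    r = np.hypot(ys - cy, xs - cx)
    return float(r.std() / r.mean())


def generate_dataset(
    class_specs: Sequence[LesionSpec],
    n_per_class: int,
    image_size: int,
    seed: int,
    out_dir: Optional[Path] = None,
) -> pd.DataFrame:
    """Generate a labelled dataset; optionally persist PNGs + metadata.csv."""
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for s in class_specs:
        s.validate()

    rows = []
    samples: List[ImageSample] = []
    idx = 0
    for spec in class_specs:
        for j in range(n_per_class):
            sid = f"c{spec.class_id}_{j:04d}"
            sample = generate_sample(spec, image_size, derive_seed(seed, idx))
            sample.sample_id = sid
            samples.append(sample)
            rows.append({
                "sample_id": sid,
                "image_path": f"images/{sid}.png",
                "mask_path": f"masks/{sid}.png",
                "label": spec.class_id,
            })
            idx += 1
    meta = pd.DataFrame(rows, columns=["sample_id", "image_path", "mask_path", "label"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        for sample, row in zip(samples, rows):
            save_image(sample.image, out_dir / row["image_path"])
            save_mask(sample.mask, out_dir / row["mask_path"])
        meta.to_csv(out_dir / "metadata.csv", index=False)
        config = {
            "master_seed": int(seed),
            "image_size": int(image_size),
            "n_per_class": int(n_per_class),
            "class_specs": [s.to_dict() for s in class_specs],
        }
        (out_dir / "config.json").write_text(json.dumps(config, indent=2))
    meta.attrs["samples"] = samples
    return meta
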