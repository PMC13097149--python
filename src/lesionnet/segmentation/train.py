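"""Segmenter training (Dice objective) and inference helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..config import SegTrainConfig
from ..data.specs import ImageSample, NormalizationStats
from ..data.transforms import normalize, resize_mask
from ..nn import AdamW, CosineSchedule, Tensor
from .ops import dice_coefficient, dice_loss_t
from .unet import UNet


def _to_batch(samples: Sequence[ImageSample], resolution: int,
              stats: Optional[NormalizationStats] = None
              ) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized NCHW image batch and N1HW mask batch."""
    xs = np.stack([
        normalize(s.image, stats, out_size=resolution).transpose(2, 0, 1)
        for s in samples
    ])
    gs = np.stack([resize_mask(s.mask, resolution)[None].astype(np.float32)
                   for s in samples])
    return xs, gs


def predict_mask(image_norm: np.ndarray, segmenter: UNet) -> np.ndarray:
    """Soft lesion-probability map for one normalized HxWx3 image."""
    if image_norm.shape[0] != image_norm.shape[1]:
        raise ValueError("expected a square working-resolution image")
    segmenter.eval()
    x = Tensor(image_norm.transpose(2, 0, 1)[None])
    return segmenter(x).data[0, 0]


def predict_masks(images_norm: np.ndarray, segmenter: UNet,
                  batch_size: int = 16) -> np.ndarray:
    """Batched inference; ``images_norm`` is (N,H,W,3) -> (N,H,W)."""
    segmenter.eval()
    outs = []
    for i in range(0, len(images_norm), batch_size):
        x = Tensor(images_norm[i:i + batch_size].transpose(0, 3, 1, 2))
        outs.append(segmenter(x).data[:, 0])
    return np.concatenate(outs, axis=0)


def train_segmenter(
    samples: Sequence[ImageSample],
    config: Optional[SegTrainConfig] = None,
    seed: int = 42,
) -> Tuple[UNet, pd.DataFrame]:
    """Train the U-Net with Dice loss; keep the best validation checkpoint.

    Returns the model (loaded with the best-epoch weights) and a per-epoch
    history frame (epoch, tr_loss, val_dice, lr).
    """
    if any(s.mask is None for s in samples):
        raise ValueError("segmenter training requires ground-truth masks")
    config = config or SegTrainConfig.desk()
    rng = np.random.default_rng(seed)
    model = UNet(rng, base=config.base_width)

    if config.max_train_samples and len(samples) > config.max_train_samples:
        pick = rng.choice(len(samples), config.max_train_samples, replace=False)
        samples = [samples[i] for i in pick]
    n = len(samples)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    x_all, g_all = _to_batch(samples, config.resolution)
    xv, gv = x_all[val_idx], g_all[val_idx]
    xt, gt = x_all[tr_idx], g_all[tr_idx]

    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    sched = CosineSchedule(config.lr, config.epochs)
    best: Dict = {"dice": -1.0, "state": model.state_dict(), "epoch": 0}
    rows: List[dict] = []

    for epoch in range(1, config.epochs + 1):
        lr = sched.apply(opt, epoch - 1)
        model.train()
        perm = rng.permutation(len(xt))
        losses = []
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i:i + config.batch_size]
            loss = dice_loss_t(model(Tensor(xt[idx])), Tensor(gt[idx]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_dice = evaluate_segmenter(model, xv, gv)
        rows.append({"epoch": epoch, "tr_loss": float(np.mean(losses)),
                     "val_dice": val_dice, "lr": lr})
        if val_dice > best["dice"]:
            best = {"dice": val_dice, "state": model.state_dict(), "epoch": epoch}

    model.load_state_dict(best["state"])
    model.eval()
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best["epoch"]
    return model, history


def evaluate_segmenter(model: UNet, x: np.ndarray, g: np.ndarray,
                       batch_size: int = 16) -> float:
    """Mean soft-Dice coefficient over a normalized NCHW batch."""
    model.eval()
    dices = []
    for i in range(0, len(x), batch_size):
        pred = model(Tensor(x[i:i + batch_size])).data
        for p, t in zip(pred[:, 0], g[i:i + batch_size, 0]):
            dices.append(dice_coefficient(p, t))
    return float(np.mean(dices))


def save_segmenter(model: UNet, path: Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    state = {k: v.tolist() for k, v in model.state_dict().items()}
    (path / "segmenter.json").write_text(
        json.dumps({"base": model.base, "state": state}))


def load_segmenter(path: Path) -> UNet:
    blob = json.loads((Path(path) / "segmenter.json").read_text())
    model = UNet(np.random.default_rng(0), base=blob["base"])
    model.load_state_dict({k: np.asarray(v, dtype=np.float32)
                           for k, v in blob["state"].items()})
    model.eval()
    return model
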