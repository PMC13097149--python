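"""Classifier training with the composite objective and early stopping."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..config import ClsTrainConfig
from ..data.specs import AugmentationParams, ImageSample
from ..data.transforms import augment, resize_mask
from ..nn import AdamW, CosineSchedule, Tensor
from ..nn import functional as F
from ..segmentation.ops import apply_mask_t, dice_loss
from ..segmentation.unet import UNet
from .losses import (attention_alignment_loss_t, confidence_penalty_t,
                     cross_entropy_t, total_loss)
from .model import LesionClassifier, LesionPipeline


def early_stop_epoch(metrics: Sequence[float], patience: int) -> int:
    """Index (1-based epoch) at which training halts: the first epoch whose
    trailing ``patience`` epochs brought no improvement; returns len(metrics)
    if training runs to the end."""
    best = -np.inf
    best_epoch = 0
    for i, m in enumerate(metrics, start=1):
        if m > best:
            best, best_epoch = m, i
        elif i - best_epoch >= patience:
            return i
    return len(metrics)


def train_classifier(
    samples: Sequence[ImageSample],
    segmenter: Optional[UNet],
    config: Optional[ClsTrainConfig] = None,
    seed: int = 42,
    val_samples: Optional[Sequence[ImageSample]] = None,
) -> Tuple[LesionPipeline, pd.DataFrame]:
    """Staged training: the segmenter stays frozen; the classifier minimizes
    l2*CE + l3*attention-alignment + l4*confidence-penalty.  The (constant)
    Dice term enters the logged total with weight l1.

    Returns the pipeline carrying the best-validation-accuracy checkpoint and
    an epoch history (epoch, tr_loss, val_loss, tr_acc, val_acc, lr, and the
    per-component columns; the l_att column only exists when l3 > 0).
    """
    config = config or ClsTrainConfig.desk()
    labels = sorted({s.label for s in samples})
    if len(labels) < 2:
        raise ValueError("classifier training needs at least 2 classes")
    label_to_idx = {c: i for i, c in enumerate(labels)}
    n_classes = len(labels)

    rng = np.random.default_rng(seed)
    model = LesionClassifier(
        n_classes, rng, backbone=config.backbone, dropout=config.dropout,
        use_attention=config.use_attention)
    pipe = LesionPipeline(segmenter, model, config)
    l1, l2, l3, l4 = config.effective_lambdas()

    if val_samples is None:
        order = rng.permutation(len(samples))
        n_val = max(1, int(round(config.val_fraction * len(samples))))
        val_samples = [samples[i] for i in order[:n_val]]
        samples = [samples[i] for i in order[n_val:]]

    xv = pipe.prepare([s.image for s in val_samples])
    yv = np.array([label_to_idx[s.label] for s in val_samples])
    mv = pipe.predict_soft_masks(xv)

    aug_params = AugmentationParams() if config.augment else None
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    sched = CosineSchedule(config.lr, config.epochs)

    best: Dict = {"acc": -1.0, "state": model.state_dict(), "epoch": 0}
    rows: List[dict] = []
    res = config.resolution

    for epoch in range(1, config.epochs + 1):
        lr = sched.apply(opt, epoch - 1)
        # fresh augmentations each epoch (geometry shared by image and mask)
        if aug_params is not None:
            epoch_samples = [
                augment(s, aug_params, int(rng.integers(2 ** 31)))
                for s in samples
            ]
        else:
            epoch_samples = list(samples)
        xt = pipe.prepare([s.image for s in epoch_samples])
        yt = np.array([label_to_idx[s.label] for s in epoch_samples])
        gt = np.stack([resize_mask(s.mask, res)[None] for s in epoch_samples])
        mt = pipe.predict_soft_masks(xt)

        model.train()
        perm = rng.permutation(len(xt))
        ep = {"l_cls": [], "l_att": [], "l_unc": [], "l_seg": [], "acc": []}
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i:i + config.batch_size]
            x = Tensor(xt[idx])
            m = Tensor(mt[idx])
            x_m = apply_mask_t(x, m, config.background_attenuation)
            out = model(x_m, dropout_rng=rng)

            l_cls = cross_entropy_t(out["log_probs"], yt[idx])
            loss = l2 * l_cls
            l_att_val = 0.0
            if model.attention is not None and l3 > 0:
                a_up = F.upsample_bilinear(out["a_s"], (res, res))
                l_att = attention_alignment_loss_t(a_up, m)
                loss = loss + l3 * l_att
                l_att_val = l_att.item()
            l_unc_val = 0.0
            if l4 > 0:
                l_unc = confidence_penalty_t(out["probs"], out["log_probs"])
                loss = loss + l4 * l_unc
                l_unc_val = l_unc.item()

            opt.zero_grad()
            loss.backward()
            opt.step()

            l_seg_val = float(np.mean([
                dice_loss(mp, gp) for mp, gp in zip(mt[idx, 0], gt[idx, 0])
            ]))
            ep["l_cls"].append(l_cls.item())
            ep["l_att"].append(l_att_val)
            ep["l_unc"].append(l_unc_val)
            ep["l_seg"].append(l_seg_val)
            ep["acc"].append(float(
                (out["probs"].data.argmax(axis=1) == yt[idx]).mean()))

        breakdown = total_loss(np.mean(ep["l_seg"]), np.mean(ep["l_cls"]),
                               np.mean(ep["l_att"]), np.mean(ep["l_unc"]),
                               (l1, l2, l3, l4))
        val_acc, val_loss = _validate(pipe, xv, mv, yv)
        row = {"epoch": epoch, "tr_loss": breakdown.l_total,
               "val_loss": val_loss, "tr_acc": float(np.mean(ep["acc"])),
               "val_acc": val_acc, "lr": lr,
               "l_seg": breakdown.l_seg, "l_cls": breakdown.l_cls,
               "l_unc": breakdown.l_unc}
        if l3 > 0:
            row["l_att"] = breakdown.l_att
        rows.append(row)

        if val_acc > best["acc"]:
            best = {"acc": val_acc, "state": model.state_dict(), "epoch": epoch}
        if epoch - best["epoch"] >= config.patience:
            break

    model.load_state_dict(best["state"])
    model.eval()
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best["epoch"]
    history.attrs["classes"] = labels
    return pipe, history


def _validate(pipe: LesionPipeline, xv: np.ndarray, mv: np.ndarray,
              yv: np.ndarray) -> Tuple[float, float]:
    pipe.classifier.eval()
    accs, losses = [], []
    for i in range(0, len(xv), 32):
        out = pipe.forward_batch(xv[i:i + 32], masks=mv[i:i + 32])
        p = out["probs"]
        accs.append(p.argmax(axis=1) == yv[i:i + 32])
        losses.append(-np.log(np.maximum(
            p[np.arange(len(p)), yv[i:i + 32]], 1e-12)))
    return (float(np.concatenate(accs).mean()),
            float(np.concatenate(losses).mean()))
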