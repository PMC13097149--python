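"""Attention classifier and the staged segment->mask->classify pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from ..config import ClsTrainConfig
from ..data.specs import ImageSample, NormalizationStats
from ..data.transforms import normalize
from ..nn import Dropout, Linear, Module, Tensor
from ..nn import functional as F
from ..segmentation.ops import apply_mask_t
from ..segmentation.unet import UNet
from .attention import AttentionModule
from .backbone import build_backbone
from .losses import ClassProbabilities


class LesionClassifier(Module):
    """Backbone -> (optional) attention -> GAP -> projection -> softmax head.

    Dropout is active only when a noise generator is supplied, which makes
    stochastic (MC) inference an explicit choice rather than a mode flag.
    """

    def __init__(self, n_classes: int, rng: np.random.Generator,
                 backbone: str = "tiny", embed_dim: int = 64,
                 dropout: float = 0.3, use_attention: bool = True,
                 backbone_bias: bool = True):
        super().__init__()
        self.n_classes = n_classes
        self.use_attention = use_attention
        self.backbone = build_backbone(backbone, rng, bias=backbone_bias)
        self.attention = AttentionModule(self.backbone.out_channels, rng) \
            if use_attention else None
        self.drop = Dropout(dropout)
        self.proj = Linear(self.backbone.out_channels, embed_dim, rng)
        self.fc = Linear(embed_dim, n_classes, rng)

    def forward(self, x_m: Tensor,
                dropout_rng: Optional[np.random.Generator] = None
                ) -> Dict[str, Tensor]:
        f = self.backbone(x_m)
        if self.attention is not None:
            f_a, a_s, a_c = self.attention(f)
        else:
            f_a, a_s, a_c = f, None, None
        pooled = F.avg_pool_global(f_a)
        if dropout_rng is not None:
            pooled = F.dropout(pooled, self.drop.p, dropout_rng, True)
        e = self.proj(pooled).relu()
        if dropout_rng is not None:
            e = F.dropout(e, self.drop.p, dropout_rng, True)
        logits = self.fc(e)
        return {"f": f, "f_a": f_a, "a_s": a_s, "a_c": a_c,
                "embedding": e, "logits": logits,
                "log_probs": F.log_softmax(logits),
                "probs": F.softmax(logits)}


def classify(f_a: np.ndarray, model: LesionClassifier) -> ClassProbabilities:
    """Head-only inference from one refined feature map (h, w, C)."""
    t = Tensor(f_a.transpose(2, 0, 1)[None])
    pooled = F.avg_pool_global(t)
    e = model.proj(pooled).relu()
    logits = model.fc(e)
    probs = F.softmax(logits).data[0]
    return ClassProbabilities(probs=probs, logits=logits.data[0],
                              embedding=e.data[0],
                              label=int(probs.argmax())).validate()


@dataclass
class PipelineOutput:
    probs: np.ndarray          # (N, C)
    masks: np.ndarray          # (N, H, W) soft predicted masks
    attention_maps: Optional[np.ndarray]   # (N, H, W) upsampled A_s or None


class LesionPipeline:
    """Frozen segmenter + classifier, operating on raw [0,1] RGB images."""

    def __init__(self, segmenter: Optional[UNet], classifier: LesionClassifier,
                 config: ClsTrainConfig,
                 stats: Optional[NormalizationStats] = None):
        self.segmenter = segmenter
        self.classifier = classifier
        self.config = config
        self.stats = stats or NormalizationStats()
        if config.use_segmentation and segmenter is None:
            raise ValueError("use_segmentation=True requires a segmenter")

    # -- preprocessing -------------------------------------------------
    def prepare(self, images: Sequence[np.ndarray]) -> np.ndarray:
        """Raw HWC images -> normalized NCHW batch at working resolution."""
        res = self.config.resolution
        return np.stack([
            normalize(im, self.stats, out_size=res).transpose(2, 0, 1)
            for im in images
        ])

    def predict_soft_masks(self, x_norm: np.ndarray) -> np.ndarray:
        """(N,3,H,W) -> (N,1,H,W) soft masks (all-ones if unsegmented)."""
        if not self.config.use_segmentation:
            n, _, h, w = x_norm.shape
            return np.ones((n, 1, h, w), dtype=np.float32)
        self.segmenter.eval()
        outs = []
        for i in range(0, len(x_norm), 16):
            outs.append(self.segmenter(Tensor(x_norm[i:i + 16])).data)
        return np.concatenate(outs, axis=0)

    # -- inference -----------------------------------------------------
    def forward_batch(self, x_norm: np.ndarray,
                      masks: Optional[np.ndarray] = None,
                      dropout_rng: Optional[np.random.Generator] = None
                      ) -> Dict[str, np.ndarray]:
        if masks is None:
            masks = self.predict_soft_masks(x_norm)
        x_m = apply_mask_t(Tensor(x_norm), Tensor(masks),
                           self.config.background_attenuation)
        out = self.classifier(x_m, dropout_rng=dropout_rng)
        res = {"probs": out["probs"].data, "logits": out["logits"].data,
               "masks": masks[:, 0]}
        if out["a_s"] is not None:
            h, w = x_norm.shape[2:]
            a_up = F.upsample_bilinear(out["a_s"], (h, w))
            res["attention_maps"] = a_up.data[:, 0]
        return res

    def predict(self, images: Sequence[np.ndarray],
                dropout_rng: Optional[np.random.Generator] = None
                ) -> PipelineOutput:
        x = self.prepare(images)
        out = self.forward_batch(x, dropout_rng=dropout_rng)
        return PipelineOutput(probs=out["probs"], masks=out["masks"],
                              attention_maps=out.get("attention_maps"))

    def predict_samples(self, samples: Sequence[ImageSample],
                        dropout_rng: Optional[np.random.Generator] = None
                        ) -> PipelineOutput:
        return self.predict([s.image for s in samples], dropout_rng=dropout_rng)
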