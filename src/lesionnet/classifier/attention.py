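"""Channel and spatial attention (squeeze-excite + channel-pooled conv)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ..nn import Conv2d, Linear, Module, Tensor, concat
from ..nn import functional as F


@dataclass
class AttentionBundle:
    """Attention products for one sample (HWC layout for user-facing arrays)."""

    spatial_map: np.ndarray       # h x w in [0, 1]
    channel_weights: np.ndarray   # C in [0, 1]
    refined_features: np.ndarray  # h x w x C
    raw_features: np.ndarray      # h x w x C

    def validate(self) -> "AttentionBundle":
        for name, arr in (("spatial_map", self.spatial_map),
                          ("channel_weights", self.channel_weights)):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} must be bounded in [0, 1]")
        if self.refined_features.shape != self.raw_features.shape:
            raise ValueError("refined/raw feature dims must match")
        return self


class AttentionModule(Module):
    """Sigmoid-gated channel (bottleneck MLP over pooled descriptors) and
    spatial (conv over channel-pooled mean/max planes) branches; the refined
    representation applies both gates to the raw features."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, spatial_kernel: int = 5):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, rng)

    def forward(self, f: Tensor) -> Tuple[Tensor, Tensor, Tensor]:
        """f: (N,C,h,w) -> (f_a, A_s (N,1,h,w), A_c (N,C))."""
        pooled = F.avg_pool_global(f)                       # (N,C)
        a_c = self.fc2(self.fc1(pooled).relu()).sigmoid()   # (N,C)

        ch_mean = f.mean(axis=1, keepdims=True)             # (N,1,h,w)
        ch_max = _channel_max(f)
        a_s = self.spatial_conv(concat([ch_mean, ch_max], axis=1)).sigmoid()

        n, c = a_c.shape
        f_a = f * a_c.reshape(n, c, 1, 1) * a_s
        return f_a, a_s, a_c


def _channel_max(f: Tensor) -> Tensor:
    """Max over channels with a winner-takes-all backward."""
    data = f.data.max(axis=1, keepdims=True)
    mask = (f.data == data)
    out = Tensor(data, requires_grad=f.requires_grad, _parents=(f,))

    def _bw(g):
        if f.requires_grad:
            counts = mask.sum(axis=1, keepdims=True)
            f._accumulate(mask * (g / counts))

    out._backward = _bw
    return out


def attend(f: np.ndarray, module: AttentionModule) -> AttentionBundle:
    """Run attention on one raw feature map (h, w, C)."""
    module.eval()
    t = Tensor(f.transpose(2, 0, 1)[None])
    f_a, a_s, a_c = module(t)
    return AttentionBundle(
        spatial_map=a_s.data[0, 0],
        channel_weights=a_c.data[0],
        refined_features=f_a.data[0].transpose(1, 2, 0),
        raw_features=np.asarray(f, dtype=np.float32),
    ).validate()
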