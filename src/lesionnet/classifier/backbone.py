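"""Convolutional feature extractors.

Backbones are registered by name.  ``tiny`` (4 conv blocks, stride 8) is
the desk-scale default.  ``efficientnet_b3`` — the full-scale choice —
needs a GPU deep-learning runtime with pretrained weights and is not
available in this CPU-only build; requesting it raises a config error.
"""

from __future__ import annotations

import numpy as np

from ..nn import Conv2d, Module, Tensor


class TinyBackbone(Module):
    """3 stride-2 blocks + 1 refinement block: 64x64x3 -> 8x8x64 (stride 8)."""

    stride = 8
    out_channels = 64

    def __init__(self, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.b1 = Conv2d(3, 16, 3, rng, stride=2, bias=bias)
        self.b2 = Conv2d(16, 32, 3, rng, stride=2, bias=bias)
        self.b3 = Conv2d(32, 64, 3, rng, stride=2, bias=bias)
        self.b4 = Conv2d(64, 64, 3, rng, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        h = self.b1(x).relu()
        h = self.b2(h).relu()
        h = self.b3(h).relu()
        return self.b4(h).relu()


class SmallBackbone(Module):
    """Wider variant of ``tiny`` (stride 8, 96 channels)."""

    stride = 8
    out_channels = 96

    def __init__(self, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.b1 = Conv2d(3, 24, 3, rng, stride=2, bias=bias)
        self.b2 = Conv2d(24, 48, 3, rng, stride=2, bias=bias)
        self.b3 = Conv2d(48, 96, 3, rng, stride=2, bias=bias)
        self.b4 = Conv2d(96, 96, 3, rng, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        h = self.b1(x).relu()
        h = self.b2(h).relu()
        h = self.b3(h).relu()
        return self.b4(h).relu()


_REGISTRY = {"tiny": TinyBackbone, "small": SmallBackbone}


def build_backbone(name: str, rng: np.random.Generator, bias: bool = True) -> Module:
    if name == "efficientnet_b3":
        raise ValueError(
            "backbone 'efficientnet_b3' requires a GPU deep-learning runtime "
            "with ImageNet weights; use 'tiny' or 'small' at desk scale"
        )
    if name not in _REGISTRY:
        raise ValueError(f"unknown backbone {name!r}; choose from {sorted(_REGISTRY)}")
    return _REGISTRY[name](rng, bias=bias)


def extract_features(x_m: np.ndarray, backbone: Module) -> np.ndarray:
    """Final-stage feature map (h, w, C) for one masked image (H, W, 3)."""
    backbone.eval()
    out = backbone(Tensor(x_m.transpose(2, 0, 1)[None]))
    return out.data[0].transpose(1, 2, 0)
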