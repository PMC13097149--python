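"""Compact encoder-decoder segmenter (depth 3, base width 16)."""

from __future__ import annotations

import numpy as np

from ..nn import Conv2d, Module, Tensor, concat
from ..nn import functional as F


class _DoubleConv(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.c2 = Conv2d(cout, cout, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).relu()).relu()


class UNet(Module):
    """3-level U-Net preceded by a stride-2 stem; the 1-channel logit map is
    bilinearly upsampled back to input resolution before the sigmoid.

    Running the trunk at half resolution keeps CPU training fast; lesion
    boundaries are smooth enough that half-resolution logits cost little
    overlap accuracy.  ~200k parameters at base=16.
    """

    def __init__(self, rng: np.random.Generator, base: int = 16, in_ch: int = 3):
        super().__init__()
        self.base = base
        self.stem = Conv2d(in_ch, base, 3, rng, stride=2)
        self.enc1 = _DoubleConv(base, base, rng)
        self.enc2 = _DoubleConv(base, base * 2, rng)
        self.bott = _DoubleConv(base * 2, base * 4, rng)
        self.up2 = Conv2d(base * 4, base * 2, 3, rng)
        self.dec2 = _DoubleConv(base * 4, base * 2, rng)
        self.up1 = Conv2d(base * 2, base, 3, rng)
        self.dec1 = _DoubleConv(base * 2, base, rng)
        self.head = Conv2d(base, 1, 1, rng, pad=0)

    def forward(self, x: Tensor) -> Tensor:
        """(N,3,H,W) -> sigmoid lesion probability (N,1,H,W)."""
        h, w = x.shape[2], x.shape[3]
        e1 = self.enc1(self.stem(x).relu())
        e2 = self.enc2(F.max_pool2d(e1))
        b = self.bott(F.max_pool2d(e2))
        d2 = self.dec2(concat([self.up2(F.upsample_nearest2(b)).relu(), e2], axis=1))
        d1 = self.dec1(concat([self.up1(F.upsample_nearest2(d2)).relu(), e1], axis=1))
        return F.upsample_bilinear(self.head(d1), (h, w)).sigmoid()
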