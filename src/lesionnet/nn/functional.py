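"""Neural-network building blocks on top of the autodiff tensor.

All spatial tensors follow the NCHW layout.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .tensor import Array, Tensor


# ---------------------------------------------------------------------------
# im2col / col2im
# ---------------------------------------------------------------------------
def _im2col(x: Array, k: int, stride: int, pad: int) -> Array:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo)


def _col2im(cols: Array, x_shape: Tuple[int, ...], k: int, stride: int, pad: int) -> Array:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


def unfold(x: Tensor, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    shape = x.shape
    out = Tensor(
        _im2col(x.data, k, stride, pad),
        requires_grad=x.requires_grad,
        _parents=(x,),
    )

    def _bw(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(_col2im(g, shape, k, stride, pad))

    out._backward = _bw
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor], stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation). weight: (Cout, Cin, k, k)."""
    n, _, h, w = x.shape
    cout, cin, k, _ = weight.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = unfold(x, k, stride, pad)                     # (N, Cin*k*k, L)
    cols = cols.transpose(0, 2, 1).reshape(n * ho * wo, cin * k * k)
    wmat = weight.reshape(cout, cin * k * k).transpose(1, 0)
    out = cols @ wmat                                    # (N*L, Cout)
    if bias is not None:
        out = out + bias.reshape(1, cout)
    return out.reshape(n, ho * wo, cout).transpose(0, 2, 1).reshape(n, cout, ho, wo)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.shape
    assert h % k == 0 and w % k == 0
    blocks = x.data.reshape(n, c, h // k, k, w // k, k)
    out_data = blocks.max(axis=(3, 5))
    # winner mask for backward; ties split gradient equally is avoided by
    # crediting only the first max via == on the block max
    mask = blocks == out_data[:, :, :, None, :, None]
    out = Tensor(out_data, requires_grad=x.requires_grad, _parents=(x,))

    def _bw(g: Array) -> None:
        if not x.requires_grad:
            return
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gb = mask * (g[:, :, :, None, :, None] / counts)
        x._accumulate(gb.reshape(n, c, h, w))

    out._backward = _bw
    return out


def avg_pool_global(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) global average pooling."""
    return x.mean(axis=(2, 3))


def upsample_nearest2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = Tensor(
        np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3),
        requires_grad=x.requires_grad,
        _parents=(x,),
    )

    def _bw(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = _bw
    return out


def _interp_matrix(n_in: int, n_out: int) -> Array:
    """Row-stochastic bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


def upsample_bilinear(x: Tensor, out_hw: Tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of (N,C,H,W) to ``out_hw``."""
    n, c, h, w = x.shape
    ho, wo = out_hw
    rh = Tensor(_interp_matrix(h, ho))
    rw = Tensor(_interp_matrix(w, wo))
    # rows: (N,C,H,W) -> (H, N*C*W) so H can be hit with a single matmul
    t = x.transpose(2, 0, 1, 3).reshape(h, n * c * w)
    t = (rh @ t).reshape(ho, n, c, w).transpose(1, 2, 0, 3)
    t = t.transpose(3, 0, 1, 2).reshape(w, n * c * ho)
    t = (rw @ t).reshape(wo, n, c, ho).transpose(1, 2, 3, 0)
    return t


def bilinear_resize(a: Array, out_hw: Tuple[int, int]) -> Array:
    """Plain-numpy bilinear resize of a 2-D array (no gradient)."""
    rh = _interp_matrix(a.shape[0], out_hw[0])
    rw = _interp_matrix(a.shape[1], out_hw[1])
    return rh @ a.astype(np.float32) @ rw.T


def dropout(x: Tensor, p: float, rng: Optional[np.random.Generator], training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    keep = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(keep)


def softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))  # detached
    e = (logits - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(logits.data.max(axis=axis, keepdims=True))
    z = logits - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
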