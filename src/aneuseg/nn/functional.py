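"""Convolutional primitives on :class:`~aneuseg.nn.tensor.Tensor`.

Feature maps use a channels-last layout ``(N, D, H, W, C)`` internally: the
im2col window view is then contiguous up to one sequential copy and the
convolution reduces to a single batched BLAS matmul, which is what makes
CPU-scale training of the 3D networks practical.  Kernel weights keep the
conventional ``(F, C, k, k, k)`` shape.  The input gradient is scattered
back by looping over the k^3 kernel offsets with strided slice adds.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv3d", "upsample_nearest", "dropout", "global_avg_pool"]


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1) -> Tensor:
    """3D convolution with 'same' zero padding and cubic odd kernel.

    ``x`` is (N, D, H, W, C); ``weight`` is (F, C, k, k, k); output spatial
    size is ``ceil(s / stride)`` per axis, output channels last.
    """
    N, D, H, W, C = x.data.shape
    F, Cw, k, _, _ = weight.data.shape
    if Cw != C:
        raise ValueError(f"input has {C} channels but kernel expects {Cw}")
    pad = k // 2

    def im2col(arr):
        # gather with channels innermost (cache-friendly), then free reshape:
        # (N, Do, Ho, Wo, k, k, k, C) -> (N, L, k^3*C)
        xp = np.pad(arr, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0))) if pad else arr
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        win = win[:, ::stride, ::stride, ::stride]
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 7, 4))
        return cols.reshape(cols.shape[0], -1, C * k ** 3), win.shape[1:4]

    cols, (Do, Ho, Wo) = im2col(x.data)
    L = Do * Ho * Wo
    w_mat = weight.data.transpose(2, 3, 4, 1, 0).reshape(C * k ** 3, F)
    out_val = (cols @ w_mat).reshape(N, Do, Ho, Wo, F)
    if bias is not None:
        out_val = out_val + bias.data
    del cols  # recomputed in backward: caching 27x the input is the memory hog

    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor.make(out_val, parents, None)
    if out.requires_grad:
        def backward(g):
            gf = g.reshape(N, L, F)
            if weight.requires_grad:
                cols, _ = im2col(x.data)
                dw_mat = np.matmul(cols.transpose(0, 2, 1), gf).sum(axis=0)
                del cols
                weight._accum(
                    dw_mat.reshape(k, k, k, C, F).transpose(4, 3, 0, 1, 2)
                )
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1, 2, 3)))
            if x.requires_grad:
                dcols = (gf @ w_mat.T).reshape(N, Do, Ho, Wo, k, k, k, C)
                gx_pad = np.zeros(
                    (N, D + 2 * pad, H + 2 * pad, W + 2 * pad, C), dtype=np.float32
                )
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            gx_pad[:,
                                   i:i + Do * stride:stride,
                                   j:j + Ho * stride:stride,
                                   l:l + Wo * stride:stride,
                                   :] += dcols[:, :, :, :, i, j, l, :]
                gx = gx_pad[:, pad:D + pad, pad:H + pad, pad:W + pad, :] if pad else gx_pad
                x._accum(gx)
        out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour spatial upsampling; backward sums over each block."""
    val = x.data
    for ax in (1, 2, 3):
        val = np.repeat(val, factor, axis=ax)
    out = Tensor.make(val, (x,), None)
    if out.requires_grad:
        N, D, H, W, C = x.data.shape

        def backward(g):
            g = g.reshape(N, D, factor, H, factor, W, factor, C)
            x._accum(g.sum(axis=(2, 4, 6)))
        out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: identity in evaluation mode."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(mask)


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean per channel -> (N, 1, 1, 1, C)."""
    return x.mean(axis=(1, 2, 3), keepdims=True)
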