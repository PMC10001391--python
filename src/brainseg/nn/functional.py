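"""Structured NHWC operations with hand-written backward passes.

Convolutions are lowered to patch extraction (``sliding_window_view``) plus a
BLAS ``tensordot``; their input gradients are scattered back with one slice-add
per kernel position, which keeps everything vectorised.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor


def _same_pad(k: int, stride: int, size: int) -> tuple[int, int]:
    """TensorFlow-style SAME padding amounts for one axis."""
    out = -(-size // stride)
    total = max(0, (out - 1) * stride + k - size)
    return total // 2, total - total // 2


def _extract_patches(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,H,W,C) -> (N,Ho,Wo,kh,kw,C) view of sliding windows."""
    win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # N,Ho',Wo',C,kh,kw
    win = win[:, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: str = "same") -> Tensor:
    """2D convolution (cross-correlation), NHWC input, (kh,kw,Cin,Cout) kernel."""
    kh, kw = w.shape[0], w.shape[1]
    if padding == "same":
        ph = _same_pad(kh, stride, x.shape[1])
        pw = _same_pad(kw, stride, x.shape[2])
    elif padding == "valid":
        ph = pw = (0, 0)
    else:
        raise ValueError(f"unknown padding {padding!r}")

    xp = np.pad(x.data, ((0, 0), ph, pw, (0, 0)))
    cols = _extract_patches(xp, kh, kw, stride)  # N,Ho,Wo,kh,kw,Cin
    out = np.tensordot(cols, w.data, axes=([3, 4, 5], [0, 1, 2]))
    if b is not None:
        out = out + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        N, Ho, Wo, _ = g.shape
        if w.requires_grad:
            w._accumulate(np.tensordot(cols, g, axes=([0, 1, 2], [0, 1, 2])))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    # grad wrt the input pixel hit by kernel tap (i, j)
                    gxp[:, i:i + Ho * stride:stride, j:j + Wo * stride:stride, :] += \
                        np.tensordot(g, w.data[i, j], axes=([3], [1]))
            H, W = x.shape[1], x.shape[2]
            x._accumulate(gxp[:, ph[0]:ph[0] + H, pw[0]:pw[0] + W, :])

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """Per-channel spatial convolution; kernel shape (kh, kw, C), SAME padding."""
    kh, kw = w.shape[0], w.shape[1]
    ph = _same_pad(kh, stride, x.shape[1])
    pw = _same_pad(kw, stride, x.shape[2])
    xp = np.pad(x.data, ((0, 0), ph, pw, (0, 0)))
    cols = _extract_patches(xp, kh, kw, stride)  # N,Ho,Wo,kh,kw,C
    out = np.einsum("nhwijc,ijc->nhwc", cols, w.data, optimize=True)
    if b is not None:
        out = out + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        N, Ho, Wo, _ = g.shape
        if w.requires_grad:
            w._accumulate(np.einsum("nhwijc,nhwc->ijc", cols, g, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + Ho * stride:stride, j:j + Wo * stride:stride, :] += \
                        g * w.data[i, j]
            H, W = x.shape[1], x.shape[2]
            x._accumulate(gxp[:, ph[0]:ph[0] + H, pw[0]:pw[0] + W, :])

    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must divide by ``size``."""
    N, H, W, C = x.shape
    if H % size or W % size:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by pool size {size}")
    Ho, Wo = H // size, W // size
    blocks = x.data.reshape(N, Ho, size, Wo, size, C).transpose(0, 1, 3, 2, 4, 5)
    flat = blocks.reshape(N, Ho, Wo, size * size, C)
    arg = flat.argmax(axis=3)
    out = np.take_along_axis(flat, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gx = gflat.reshape(N, Ho, Wo, size, size, C).transpose(0, 1, 3, 2, 4, 5)
        x._accumulate(gx.reshape(N, H, W, C))

    return Tensor._make(out, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=1).repeat(2, axis=2)

    def backward(g):
        N, Ho, Wo, C = g.shape
        gx = g.reshape(N, Ho // 2, 2, Wo // 2, 2, C).sum(axis=(2, 4))
        x._accumulate(gx)

    return Tensor._make(out, (x,), backward)


def _linear_coeffs(out_size: int, in_size: int):
    """Half-pixel-centre linear interpolation indices/weights for 2x scaling."""
    src = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, in_size - 1)
    i1 = np.clip(i0 + 1, 0, in_size - 1)
    w1 = np.clip(src - i0, 0.0, 1.0).astype(np.float32)
    return i0, i1, (1.0 - w1), w1


def upsample_bilinear2x(x: Tensor) -> Tensor:
    N, H, W, C = x.shape
    i0, i1, wa, wb = _linear_coeffs(2 * H, H)
    j0, j1, va, vb = _linear_coeffs(2 * W, W)
    rows = x.data[:, i0] * wa[None, :, None, None] + x.data[:, i1] * wb[None, :, None, None]
    out = rows[:, :, j0] * va[None, None, :, None] + rows[:, :, j1] * vb[None, None, :, None]

    def backward(g):
        grows = np.zeros((N, 2 * H, W, C), dtype=g.dtype)
        np.add.at(grows, (slice(None), slice(None), j0), g * va[None, None, :, None])
        np.add.at(grows, (slice(None), slice(None), j1), g * vb[None, None, :, None])
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), i0), grows * wa[None, :, None, None])
        np.add.at(gx, (slice(None), i1), grows * wb[None, :, None, None])
        x._accumulate(gx)

    return Tensor._make(out, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N, H, W); updates running stats in place."""
    axes = tuple(range(x.ndim - 1))
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = gamma.data * xhat + beta.data
    m = x.data.size // x.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data
            if training:
                gx = inv_std / m * (
                    m * dxhat
                    - dxhat.sum(axis=axes)
                    - xhat * (dxhat * xhat).sum(axis=axes)
                )
            else:
                gx = dxhat * inv_std
            x._accumulate(gx)

    return Tensor._make(out, (x, gamma, beta), backward)
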