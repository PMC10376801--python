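"""Differentiable building blocks on top of the autograd core.

Convolution is implemented as a loop over the ``kh*kw`` kernel offsets, each
offset contributing one small ``tensordot`` — on the feature-map sizes this
package works with that is faster and far simpler than im2col, and the
backward pass mirrors it exactly.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "conv2d",
    "bilinear_resize",
    "l2_normalize",
    "sinusoidal_position_encoding",
]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on a single image via im2col.

    Parameters
    ----------
    x : Tensor, shape (C_in, H, W)
    weight : Tensor, shape (C_out, C_in, kh, kw)
    bias : Tensor of shape (C_out,) or None
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    if padding:
        xp = np.zeros((cin, h + 2 * padding, w + 2 * padding), dtype=np.float32)
        xp[:, padding:padding + h, padding:padding + w] = x.data
    else:
        xp = np.ascontiguousarray(x.data, dtype=np.float32)
    hp, wp = xp.shape[1:]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    # (cin, ho, wo, kh, kw) strided view -> one (cin*kh*kw, ho*wo) GEMM operand
    windows = np.lib.stride_tricks.sliding_window_view(
        xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    col = np.ascontiguousarray(windows.transpose(0, 3, 4, 1, 2)).reshape(
        cin * kh * kw, ho * wo)
    w_mat = weight.data.reshape(cout, cin * kh * kw)
    out = (w_mat @ col).reshape(cout, ho, wo)
    if bias is not None:
        out += bias.data[:, None, None]

    parents = [x, weight] + ([bias] if bias is not None else [])

    def backward(g: np.ndarray) -> None:
        g_mat = g.reshape(cout, ho * wo)
        if weight.requires_grad:
            weight._accumulate((g_mat @ col.T).reshape(weight.data.shape))
        if x.requires_grad:
            dcol = (w_mat.T @ g_mat).reshape(cin, kh, kw, ho, wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += dcol[:, i, j]
            if padding:
                gxp = gxp[:, padding:padding + h, padding:padding + w]
            x._accumulate(gxp)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2)))

    return Tensor._make(out, parents, backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    mat[np.arange(n_out), lo] += (1.0 - frac).astype(np.float32)
    mat[np.arange(n_out), hi] += frac.astype(np.float32)
    return mat


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of a (C, H, W) tensor to ``out_hw``.

    Implemented as two constant linear maps, so the gradient is their
    transpose; a constant map resizes to the same constant exactly.
    """
    x = as_tensor(x)
    c, h, w = x.shape
    ho, wo = out_hw
    if (h, w) == (ho, wo):
        return x
    ah = _interp_matrix(ho, h)
    aw = _interp_matrix(wo, w)
    out = (ah @ x.data) @ aw.T          # broadcast over the channel axis

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(ah.T @ (g @ aw))

    return Tensor._make(out, (x,), backward)


def l2_normalize(x: Tensor, axis: int = 0, eps: float = 1e-8) -> Tensor:
    """Unit-normalize along ``axis`` (composite op; differentiable)."""
    x = as_tensor(x)
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps) ** 0.5
    return x / norm


def sinusoidal_position_encoding(dim: int, h: int, w: int) -> np.ndarray:
    """Fixed 2-D sine/cosine positional code of shape (dim, h, w).

    Half of the channels encode the row coordinate, half the column, each
    with geometrically spaced frequencies, so absolute position is available
    to the attention layers without any learned parameters.
    """
    if dim % 4 != 0:
        raise ValueError("position encoding dim must be a multiple of 4")
    quarter = dim // 4
    freqs = np.exp(-np.log(10000.0) * np.arange(quarter) / max(quarter, 1))
    ys = np.arange(h)[:, None] * freqs[None, :]      # (h, quarter)
    xs = np.arange(w)[:, None] * freqs[None, :]      # (w, quarter)
    pe = np.zeros((dim, h, w), dtype=np.float32)
    pe[0 * quarter:1 * quarter] = np.sin(ys).T[:, :, None]
    pe[1 * quarter:2 * quarter] = np.cos(ys).T[:, :, None]
    pe[2 * quarter:3 * quarter] = np.sin(xs).T[:, None, :]
    pe[3 * quarter:4 * quarter] = np.cos(xs).T[:, None, :]
    return pe
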