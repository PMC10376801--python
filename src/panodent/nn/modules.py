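"""Neural-network layers: linear, conv, layer norm and multi-head attention.

All parameters are created from an explicit ``numpy.random.Generator`` so two
modules built with the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .functional import conv2d

__all__ = [
    "Module", "Linear", "Conv2d", "LayerNorm", "FeedForward",
    "MultiheadAttention", "ResidualConvBlock",
]


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Tensor] = []
        for v in value:
            out.extend(_collect(v))
        return out
    if isinstance(value, dict):
        out = []
        for v in value.values():
            out.extend(_collect(v))
        return out
    return []


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...], gain: float = 1.0) -> np.ndarray:
    bound = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out), dtype=np.float32)
        else:
            w = _xavier(rng, d_in, d_out, (d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (..., d_in); collapse leading dims for the matmul
        shape = x.shape
        flat = x.reshape(-1, shape[-1]) if x.ndim != 2 else x
        out = flat @ self.weight + self.bias
        if x.ndim != 2:
            out = out.reshape(*shape[:-1], self.weight.shape[1])
        return out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None, zero_init: bool = False):
        if padding is None:
            padding = kernel // 2
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel), dtype=np.float32)
        else:
            w = _xavier(rng, fan_in, fan_out, (c_out, c_in, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class FeedForward(Module):
    """Two-layer MLP whose second projection is zero-initialized, so a fresh
    block leaves its residual stream untouched."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class MultiheadAttention(Module):
    """Scaled dot-product attention with learned projections.

    Accepts token arrays of shape ``(T, D)`` or batched ``(B, T, D)``; query
    and key/value sources may differ (cross-attention).  The output
    projection is zero-initialized by default so that, wrapped in a residual
    connection, an untrained attention layer is the identity.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 zero_out_proj: bool = True):
        if dim % n_heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng, zero_init=zero_out_proj)

    def _split(self, x: Tensor, b: int, t: int) -> Tensor:
        # (B, T, D) -> (B*heads, T, head_dim)
        return (x.reshape(b, t, self.n_heads, self.head_dim)
                 .transpose(0, 2, 1, 3)
                 .reshape(b * self.n_heads, t, self.head_dim))

    def __call__(self, query: Tensor, key_value: Tensor | None = None) -> Tensor:
        if key_value is None:
            key_value = query
        squeeze = query.ndim == 2
        q = query.reshape(1, *query.shape) if squeeze else query
        kv = key_value.reshape(1, *key_value.shape) if key_value.ndim == 2 else key_value
        b, tq, d = q.shape
        tk = kv.shape[1]
        qh = self._split(self.q_proj(q), b, tq)
        kh = self._split(self.k_proj(kv), b, tk)
        vh = self._split(self.v_proj(kv), b, tk)
        scores = (qh @ kh.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)
        ctx = attn @ vh                                   # (B*h, Tq, hd)
        ctx = (ctx.reshape(b, self.n_heads, tq, self.head_dim)
                  .transpose(0, 2, 1, 3)
                  .reshape(b, tq, d))
        out = self.out_proj(ctx)
        return out.reshape(tq, d) if squeeze else out


class ResidualConvBlock(Module):
    """conv-relu-conv with a skip connection; optional stride / channel change."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1):
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride)
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.proj = (Conv2d(c_in, c_out, 1, rng, stride=stride, padding=0)
                     if (stride != 1 or c_in != c_out) else None)

    def __call__(self, x: Tensor) -> Tensor:
        skip = self.proj(x) if self.proj is not None else x
        return (self.conv2(self.conv1(x).relu()) + skip).relu()
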