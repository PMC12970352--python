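"""Neural-network building blocks on top of :mod:`beast.nn.tensor`.

Modules hold named ``Tensor`` parameters and expose ``parameters()`` /
``state_dict()`` for optimization and checkpointing.  Initialization is
truncated-normal and fully seeded: every module takes an ``rng``
(``numpy.random.Generator``) at construction.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MLP",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Conv1d",
    "trunc_normal",
    "sinusoidal_position_embeddings",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal draws truncated at ±2 std (re-drawn), as in common ViT init."""
    x = rng.standard_normal(shape)
    bad = np.abs(x) > 2.0
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(x) > 2.0
    return x * std


def sinusoidal_position_embeddings(n_positions: int, dim: int) -> np.ndarray:
    """Fixed 1-D sine/cosine position table of shape (n_positions, dim)."""
    pos = np.arange(n_positions, dtype=np.float64)[:, None]
    i = np.arange(dim // 2, dtype=np.float64)[None, :]
    angles = pos / (10000.0 ** (2.0 * i / dim))
    emb = np.zeros((n_positions, dim))
    emb[:, 0::2] = np.sin(angles)
    emb[:, 1::2] = np.cos(angles)
    return emb


class Module:
    """Base class: child modules and Tensor attributes are tracked by name."""

    def parameters(self):
        out = []
        for _, p in self.named_parameters():
            out.append(p)
        return out

    def named_parameters(self, prefix: str = ""):
        items = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                items.append((full, val))
            elif isinstance(val, Module):
                items.extend(val.named_parameters(prefix=full + "."))
            elif isinstance(val, (list, tuple)):
                for k, item in enumerate(val):
                    if isinstance(item, Module):
                        items.extend(item.named_parameters(prefix=f"{full}.{k}."))
        return items

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map; default init is fan-in scaled truncated normal, which
    preserves activation scale through deep stacks at desk-scale widths."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, std: float | None = None):
        if std is None:
            std = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(trunc_normal(rng, (d_in, d_out), std), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gain + self.shift


class MLP(Module):
    """Two-layer GELU MLP (transformer feed-forward / projector)."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng):
        if dim % heads != 0:
            raise ValueError(f"token width {dim} not divisible by {heads} heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, S, D = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(B, S, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # each (B, h, S, hd)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, S, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm transformer encoder block."""

    def __init__(self, dim: int, heads: int, rng, mlp_ratio: float = 4.0):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.mlp(self.norm2(x))
        return x


class Conv1d(Module):
    """Temporal convolution along axis 0 with replicate ('same') padding.

    Input is (T, C_in); each output step sees a centered window of
    ``kernel`` steps.  Implemented as a window gather followed by a matmul,
    so the autodiff graph only contains primitive ops.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        if kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        self.kernel = kernel
        self.c_in = c_in
        self.weight = Tensor(
            trunc_normal(rng, (kernel * c_in, c_out), std=1.0 / np.sqrt(kernel * c_in)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        T = x.shape[0]
        half = self.kernel // 2
        idx = np.clip(np.arange(T)[:, None] + np.arange(-half, half + 1)[None, :], 0, T - 1)
        windows = x[idx]                          # (T, kernel, C_in)
        flat = windows.reshape(T, self.kernel * self.c_in)
        return flat @ self.weight + self.bias
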