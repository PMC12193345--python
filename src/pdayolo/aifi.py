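"""Attention-based Intra-scale Feature Interaction (AIFI).

Replaces the SPPF stage at the deepest backbone level: the h x w x c map
is flattened to h*w tokens, 2-D sinusoidal positional encodings are added
to the query/key inputs, and a post-norm transformer encoder layer is
applied:

    attn = softmax(Q K^T / sqrt(d_k)) V           (multi-head)
    y    = LN(x + MHSA(x + pos, x + pos, x))
    out  = LN(y + MLP(y)),   MLP = Linear(c -> hidden), GELU, Linear(hidden -> c)

Defaults: 8 heads, hidden width 512 for 256-dim tokens, temperature 10000.
No dropout; the block is deterministic given its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn import LayerNorm, Linear, Module, Tensor


@dataclass
class PosEmbed:
    embed_dim: int
    temperature: float = 10000.0

    def __post_init__(self):
        if self.embed_dim % 4:
            raise ValueError("embed_dim must be divisible by 4")


def build_2d_sincos_pos_embed(h: int, w: int, p: PosEmbed) -> np.ndarray:
    """(h*w, embed_dim) grid encoding; quarters hold sin/cos of the x and y
    position frequencies, so every token has squared norm embed_dim / 2."""
    d = p.embed_dim
    quarter = d // 4
    omega = 1.0 / (p.temperature ** (np.arange(quarter) / quarter))
    gx, gy = np.meshgrid(np.arange(w, dtype=np.float64),
                         np.arange(h, dtype=np.float64))
    out_x = gx.reshape(-1, 1) * omega[None, :]
    out_y = gy.reshape(-1, 1) * omega[None, :]
    emb = np.concatenate(
        [np.sin(out_x), np.cos(out_x), np.sin(out_y), np.cos(out_y)], axis=1)
    return emb.astype(np.float32)


@dataclass
class AttentionBatch:
    """Explicit Q/K/V carrier for the bare attention operation."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    d_k: int
    heads: int = 1


def scaled_dot_attention(b: AttentionBatch) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V on plain arrays; rows sum to one."""
    logits = b.Q @ b.K.swapaxes(-1, -2) / np.sqrt(b.d_k)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ b.V


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.dk = dim, heads, dim // heads
        self.wq = Linear(dim, dim)
        self.wk = Linear(dim, dim)
        self.wv = Linear(dim, dim)
        self.wo = Linear(dim, dim)

    def forward(self, q_in: Tensor, k_in: Tensor, v_in: Tensor) -> Tensor:
        n, l, d = q_in.shape

        def split(t):  # (N, L, D) -> (N, H, L, dk)
            return ag.transpose(t.reshape(n, l, self.heads, self.dk), (0, 2, 1, 3))

        q, k, v = split(self.wq(q_in)), split(self.wk(k_in)), split(self.wv(v_in))
        attn = ag.softmax(q @ ag.transpose(k, (0, 1, 3, 2)) * (self.dk ** -0.5), axis=-1)
        out = ag.transpose(attn @ v, (0, 2, 1, 3)).reshape(n, l, d)
        return self.wo(out)


class AIFI(Module):
    def __init__(self, c: int, heads: int = 8, hidden: int = 512,
                 temperature: float = 10000.0):
        super().__init__()
        self.pos = PosEmbed(c, temperature)
        self.attn = MultiHeadSelfAttention(c, heads)
        self.norm1 = LayerNorm(c, axis=-1)
        self.norm2 = LayerNorm(c, axis=-1)
        self.fc1 = Linear(c, hidden)
        self.fc2 = Linear(hidden, c)
        self.c = c

    def forward(self, x: Tensor, use_pos: bool = True) -> Tensor:
        n, c, h, w = x.shape
        if c != self.c:
            raise ValueError(f"AIFI expects {self.c} channels, got {c}")
        tokens = ag.transpose(x.reshape(n, c, h * w), (0, 2, 1))  # (N, L, C)
        if use_pos:
            pos = Tensor(build_2d_sincos_pos_embed(h, w, self.pos)[None])
            qk = tokens + pos
        else:
            qk = tokens
        y = self.norm1(tokens + self.attn(qk, qk, tokens))
        y = self.norm2(y + self.fc2(ag.gelu(self.fc1(y))))
        return ag.transpose(y, (0, 2, 1)).reshape(n, c, h, w)


def aifi_forward(x, p: PosEmbed | None = None, module: AIFI | None = None,
                 use_pos: bool = True) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    if module is None:
        c = x.shape[1]
        module = AIFI(c, temperature=p.temperature if p else 10000.0)
    return module(x, use_pos=use_pos)
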