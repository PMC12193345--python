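"""Building blocks: baseline YOLO11 units and their PoolFormer variants.

The baseline family (Bottleneck, C3k, C3k2, SPPF, C2PSA) follows the
YOLO11 design: C3k2 splits its input with a pointwise conv, routes one
partial path through ``n`` inner blocks — C3k sub-blocks when its boolean
switch is true, Bottlenecks when false — and fuses everything with a
second pointwise conv.

The PoolFormer variants keep the identical split/fuse topology and swap
only the inner blocks: PF_C3k2(false) replaces each Bottleneck with a
PoolFormer block, PF_C3k2(true) routes through PF_C3k, a C3k whose
Bottlenecks are replaced by PoolFormer blocks.  A PoolFormer block is a
metaformer with average pooling as its token mixer:

    y   = x + (AvgPool3x3(LN(x)) - LN(x))
    out = y + MLP(LN(y)),   MLP = 1x1 conv (c -> m*c), GELU, 1x1 conv (m*c -> c)

LayerNorm acts along the channel axis at each spatial location; the 3x3
average pool uses stride 1 and a divisor that counts only in-image cells,
so a spatially constant map is a fixed point of the mixer input stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import autograd as ag
from .nn import (ConvBNAct, DSConv, LayerNorm, Module, Conv2d, Tensor)


@dataclass
class BlockConfig:
    """Configuration for a single block forward (spec-level contract)."""

    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1
    repeat_n: int = 1          # inner-block repeats; the network uses 1
    mode_flag: bool = False    # True -> (PF_)C3k inner path, False -> Bottleneck/PoolFormer
    mlp_expansion: float = 4.0

    def __post_init__(self):
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        if self.repeat_n < 1:
            raise ValueError("repeat_n must be >= 1")
        if self.mlp_expansion <= 0:
            raise ValueError("mlp_expansion must be positive")


class Bottleneck(Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True, e: float = 0.5,
                 k=(3, 3)):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNAct(c1, c_, k[0])
        self.cv2 = ConvBNAct(c_, c2, k[1])
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class PoolFormerBlock(Module):
    """Metaformer block with a parameter-free average-pooling token mixer."""

    def __init__(self, c: int, mlp_expansion: float = 4.0):
        super().__init__()
        hidden = int(round(c * mlp_expansion))
        self.norm1 = LayerNorm(c, axis=1)
        self.norm2 = LayerNorm(c, axis=1)
        self.fc1 = Conv2d(c, hidden, 1)
        self.fc2 = Conv2d(hidden, c, 1)

    def token_mix(self, t: Tensor) -> Tensor:
        return ag.local_avg_pool(t, 3) - t

    def forward(self, x: Tensor) -> Tensor:
        y = x + self.token_mix(self.norm1(x))
        return y + self.fc2(ag.gelu(self.fc1(self.norm2(y))))


class C3k(Module):
    """CSP block with two inner 3x3 Bottlenecks and a fusing conv."""

    def __init__(self, c1: int, c2: int, n: int = 2, shortcut: bool = True,
                 e: float = 0.5, inner: str = "bottleneck", mlp_expansion: float = 4.0):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBNAct(c1, c_, 1)
        self.cv2 = ConvBNAct(c1, c_, 1)
        self.cv3 = ConvBNAct(2 * c_, c2, 1)
        if inner == "bottleneck":
            self.m = [Bottleneck(c_, c_, shortcut, e=1.0) for _ in range(n)]
        elif inner == "poolformer":
            self.m = [PoolFormerBlock(c_, mlp_expansion) for _ in range(n)]
        else:
            raise ValueError(f"unknown inner block {inner!r}")

    def forward(self, x: Tensor) -> Tensor:
        a = self.cv1(x)
        for m in self.m:
            a = m(a)
        return self.cv3(ag.concat([a, self.cv2(x)], axis=1))


class PFC3k(C3k):
    """C3k with its Bottlenecks replaced by PoolFormer blocks."""

    def __init__(self, c1, c2, n=2, e=0.5, mlp_expansion: float = 4.0):
        super().__init__(c1, c2, n, e=e, inner="poolformer", mlp_expansion=mlp_expansion)


class C3k2(Module):
    """Split/partial-path block: pointwise split, n inner blocks on the live
    branch (C3k if ``c3k`` else Bottleneck), concat of all partials, pointwise
    fusion."""

    inner_false = staticmethod(lambda c, mlp: Bottleneck(c, c, True, e=0.5))
    inner_true = staticmethod(lambda c, mlp: C3k(c, c, 2))

    def __init__(self, c1: int, c2: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, mlp_expansion: float = 4.0):
        super().__init__()
        self.c = int(c2 * e)
        self.c3k = c3k
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1)
        self.cv2 = ConvBNAct((2 + n) * self.c, c2, 1)
        make = self.inner_true if c3k else self.inner_false
        self.m = [make(self.c, mlp_expansion) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        a, b = ag.chunk(self.cv1(x), 2, axis=1)
        ys = [a, b]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(ag.concat(ys, axis=1))


class PFC3k2(C3k2):
    """C3k2 with PoolFormer inner blocks: PF_C3k on the true path, a single
    PoolFormer block where the baseline has a Bottleneck on the false path."""

    inner_false = staticmethod(lambda c, mlp: PoolFormerBlock(c, mlp))
    inner_true = staticmethod(lambda c, mlp: PFC3k(c, c, 2, mlp_expansion=mlp))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three cascaded k x k max pools."""

    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBNAct(c1, c_, 1)
        self.cv2 = ConvBNAct(c_ * 4, c2, 1)
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ag.max_pool(y[-1], self.k, 1, self.k // 2))
        return self.cv2(ag.concat(y, axis=1))


class _ConvAttention(Module):
    """Conv-projected multi-head self-attention used inside C2PSA."""

    def __init__(self, dim: int, num_heads: int, attn_ratio: float = 0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = ConvBNAct(dim, h, 1, act=False)
        self.proj = ConvBNAct(dim, dim, 1, act=False)
        self.pe = ConvBNAct(dim, dim, 3, g=dim, act=False)
        self.dim, self.nh_kd = dim, nh_kd

    def forward(self, x: Tensor) -> Tensor:
        n, c, hh, ww = x.shape
        l = hh * ww
        qkv = self.qkv(x)
        q = ag.narrow(qkv, 1, 0, self.nh_kd).reshape(n, self.num_heads, self.key_dim, l)
        k = ag.narrow(qkv, 1, self.nh_kd, self.nh_kd).reshape(n, self.num_heads, self.key_dim, l)
        v = ag.narrow(qkv, 1, 2 * self.nh_kd, self.dim)
        v4 = v.reshape(n, self.num_heads, self.head_dim, l)
        attn = ag.softmax(ag.transpose(q, (0, 1, 3, 2)) @ k * self.scale, axis=-1)
        out = v4 @ ag.transpose(attn, (0, 1, 3, 2))
        out = out.reshape(n, c, hh, ww) + self.pe(v.reshape(n, c, hh, ww))
        return self.proj(out)


class _PSABlock(Module):
    def __init__(self, c: int, num_heads: int):
        super().__init__()
        self.attn = _ConvAttention(c, num_heads)
        self.ffn = [ConvBNAct(c, c * 2, 1), ConvBNAct(c * 2, c, 1, act=False)]

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(x)
        return x + self.ffn[1](self.ffn[0](x))


class C2PSA(Module):
    """Partial self-attention stage at the end of the backbone."""

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5):
        super().__init__()
        self.c = int(c1 * e)
        self.cv1 = ConvBNAct(c1, 2 * self.c, 1)
        self.cv2 = ConvBNAct(2 * self.c, c1, 1)
        self.m = [_PSABlock(self.c, max(1, self.c // 64)) for _ in range(n)]

    def forward(self, x: Tensor) -> Tensor:
        a, b = ag.chunk(self.cv1(x), 2, axis=1)
        for m in self.m:
            b = m(b)
        return self.cv2(ag.concat([a, b], axis=1))


# ----------------------------------------------------- spec-level operations
def _to_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def dsconv_forward(x, cfg: BlockConfig, module: DSConv | None = None) -> Tensor:
    """Depthwise separable convolution forward (stride 1, same padding)."""
    x = _to_tensor(x)
    if module is None:
        module = DSConv(cfg.in_channels, cfg.out_channels, cfg.kernel)
    return module(x)


def poolformer_forward(x, cfg: BlockConfig, module: PoolFormerBlock | None = None) -> Tensor:
    x = _to_tensor(x)
    if cfg.in_channels != cfg.out_channels:
        raise ValueError("PoolFormer block requires in_channels == out_channels")
    if module is None:
        module = PoolFormerBlock(cfg.in_channels, cfg.mlp_expansion)
    return module(x)


def baseline_c3k2_forward(x, cfg: BlockConfig, module: C3k2 | None = None) -> Tensor:
    x = _to_tensor(x)
    if module is None:
        module = C3k2(cfg.in_channels, cfg.out_channels, cfg.repeat_n, cfg.mode_flag)
    return module(x)


def pf_c3k2_forward(x, cfg: BlockConfig, module: PFC3k2 | None = None) -> Tensor:
    x = _to_tensor(x)
    if module is None:
        module = PFC3k2(cfg.in_channels, cfg.out_channels, cfg.repeat_n,
                        cfg.mode_flag, mlp_expansion=cfg.mlp_expansion)
    return module(x)
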