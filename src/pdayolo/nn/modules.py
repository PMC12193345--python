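"""Layer modules built on the autograd engine.

Naming follows the host-detector idiom: ``ConvBNAct`` is the standard
conv + batch-norm + SiLU unit, ``DWConv`` its depthwise variant, and
``DSConv`` a depthwise separable convolution (depthwise k x k followed by
pointwise 1 x 1) with plain biases and no normalization, as used inside
the edge-enhancement module.
"""

from __future__ import annotations

import hashlib

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor


class Module:
    """Minimal nn.Module analogue: parameter registration by attribute walk."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def param_checksum(self) -> str:
        """Deterministic digest of all parameter values (order-stable)."""
        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data, dtype=np.float64).tobytes())
        return h.hexdigest()


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


# --------------------------------------------------------------------- init
_INIT_RNG: list[np.random.Generator] = []


class init_scope:
    """Context manager giving all layers built inside it a shared seeded RNG."""

    def __init__(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def __enter__(self):
        _INIT_RNG.append(self.rng)
        return self.rng

    def __exit__(self, *exc):
        _INIT_RNG.pop()
        return False


def _rng() -> np.random.Generator:
    if _INIT_RNG:
        return _INIT_RNG[-1]
    return np.random.default_rng()


def kaiming(shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (_rng().standard_normal(shape) * std).astype(np.float32)


# ------------------------------------------------------------------- layers
class Conv2d(Module):
    """Bare convolution with optional bias; no normalization, no activation."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None,
                 g: int = 1, bias: bool = True):
        super().__init__()
        if k % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {k}")
        if c1 % g or c2 % g:
            raise ValueError(f"channels ({c1}->{c2}) not divisible by groups {g}")
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.p = k // 2 if p is None else p
        self.weight = Parameter(kaiming((c2, c1 // g, k, k), fan_in=(c1 // g) * k * k))
        self.bias = Parameter(np.zeros(c2, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c1:
            raise ValueError(f"expected {self.c1} input channels, got {x.shape[1]}")
        return ag.conv2d(x, self.weight, self.bias, self.s, self.p, self.g)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)


class LayerNorm(Module):
    """Normalization along one axis (channel axis 1 for NCHW maps,
    feature axis -1 for token sequences)."""

    def __init__(self, c: int, axis: int = 1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.axis, self.eps = axis, eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta, self.axis, self.eps)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(kaiming((out_f, in_f), fan_in=in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class ConvBNAct(Module):
    """Standard detector conv unit: conv (no bias) + batch norm + SiLU."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None,
                 g: int = 1, act: bool = True):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, g, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return ag.silu(y) if self.act else y


class DWConv(ConvBNAct):
    """Depthwise conv unit (groups = channels)."""

    def __init__(self, c1: int, c2: int, k: int = 3, s: int = 1, act: bool = True):
        super().__init__(c1, c2, k, s, g=np.gcd(c1, c2), act=act)


class DSConv(Module):
    """Depthwise separable convolution: depthwise k x k then pointwise 1 x 1.

    Plain biased convolutions with no normalization or activation; callers
    (e.g. the edge-enhancement module) apply their own nonlinearity.
    """

    def __init__(self, c1: int, c2: int, k: int = 3, s: int = 1, bias: bool = True):
        super().__init__()
        self.dw = Conv2d(c1, c1, k, s, g=c1, bias=bias)
        self.pw = Conv2d(c1, c2, 1, 1, bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        return self.pw(self.dw(x))


# ---------------------------------------------------------------- optimizer
class SGD:
    """SGD with momentum and decoupled-from-nothing classic weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 0.0005):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
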