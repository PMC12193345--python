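"""Dynamic Multi-scale Aware Edge (DMAE) module.

Small insects in trap-bottle images are separated from grain clutter
mostly by their boundaries, so the module enhances high-frequency (edge)
content at several spatial resolutions and fuses it with a local branch
under input-dependent scalar weights:

    F_edge = F_in - avgpool_3x3(F_in)                       (EFE high-pass)
    F_out  = F_in + sigmoid(DSConv_3x3(F_edge))             (EFE refinement)

    F_local = W_0 * DSConv_3x3(x)
    F_i     = W_i * EdgeBranch_i(x),  i = 1..n
    F_c     = Conv_1x1(Concat[F_local, F_1, ..., F_n])

Each edge-aware branch adaptively average-pools the map down to r_i x r_i
(feat_rls, default [3, 6, 9, 12]), reduces channels with a 1x1 conv,
extracts features with a 3x3 depthwise-separable conv, applies EFE, and
bilinearly upsamples back to the input resolution.  The Complexity-based
Weight Generator (CWG) produces the n+1 branch weights from globally
pooled features through a small pointwise conv stack with a final sigmoid,
so every weight is strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autograd as ag
from .nn import Conv2d, ConvBNAct, DSConv, Module, Tensor


@dataclass
class DMAEConfig:
    in_channels: int
    out_channels: int | None = None      # None -> channel-preserving
    feat_rls: list[int] = field(default_factory=lambda: [3, 6, 9, 12])
    reduction: int = 2

    def __post_init__(self):
        if self.out_channels is None:
            self.out_channels = self.in_channels
        rls = list(self.feat_rls)
        if any(r < 1 for r in rls) or any(b <= a for a, b in zip(rls, rls[1:])):
            raise ValueError("feat_rls must be strictly increasing and >= 1")
        if self.in_channels % self.reduction:
            raise ValueError("in_channels must be divisible by reduction")

    @property
    def n(self) -> int:
        return len(self.feat_rls)


@dataclass
class BranchWeights:
    """Scalar gate per branch, each strictly in (0, 1)."""

    w_local: np.ndarray   # (N,)
    w_edge: np.ndarray    # (N, n)


def _to_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class EFE(Module):
    """Edge Feature Enhancement: high-pass by mean subtraction, then a
    sigmoid-normalized depthwise-separable refinement added residually."""

    def __init__(self, c: int):
        super().__init__()
        self.ds = DSConv(c, c, 3)

    def edge_map(self, f_in: Tensor) -> Tensor:
        return f_in - ag.local_avg_pool(f_in, 3)

    def forward(self, f_in: Tensor) -> Tensor:
        return f_in + ag.sigmoid(self.ds(self.edge_map(f_in)))


class EdgeBranch(Module):
    """One edge-aware branch at target resolution r."""

    def __init__(self, c_in: int, c_out: int, r: int):
        super().__init__()
        self.r = r
        self.reduce = ConvBNAct(c_in, c_out, 1)
        self.extract = DSConv(c_out, c_out, 3)
        self.efe = EFE(c_out)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if self.r > h or self.r > w:
            raise ValueError(
                f"edge branch resolution {self.r} exceeds input size {h}x{w}")
        y = ag.adaptive_avg_pool(x, (self.r, self.r))
        y = self.efe(self.extract(self.reduce(y)))
        return ag.upsample_bilinear(y, (h, w))


class CWG(Module):
    """Complexity-based Weight Generator: GAP -> 1x1 conv stack -> sigmoid,
    one independent scalar weight per branch (n edge branches + local)."""

    def __init__(self, c: int, n_branches: int, squeeze: int = 8):
        super().__init__()
        hidden = max(1, c // squeeze)
        self.fc1 = Conv2d(c, hidden, 1)
        self.fc2 = Conv2d(hidden, n_branches, 1)

    def forward(self, x: Tensor) -> Tensor:
        g = ag.adaptive_avg_pool(x, (1, 1))
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(g))))  # (N, n+1, 1, 1)


class DMAE(Module):
    def __init__(self, cfg: DMAEConfig):
        super().__init__()
        self.cfg = cfg
        c, rho = cfg.in_channels, cfg.reduction
        # all branches (local included) emit c/rho channels so the weighted
        # concat treats them symmetrically
        self.local = DSConv(c, c // rho, 3)
        self.branches = [EdgeBranch(c, c // rho, r) for r in cfg.feat_rls]
        self.cwg = CWG(c, cfg.n + 1)
        self.fuse = ConvBNAct((cfg.n + 1) * (c // rho), cfg.out_channels, 1)

    def branch_weights(self, x: Tensor) -> Tensor:
        return self.cwg(x)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"DMAE expects {self.cfg.in_channels} channels, got {x.shape[1]}")
        h, w = x.shape[2], x.shape[3]
        weights = self.cwg(x)  # (N, n+1, 1, 1)
        outs = [ag.narrow(weights, 1, 0, 1) * self.local(x)]
        for i, br in enumerate(self.branches):
            # branch resolutions are clamped to the current map size so the
            # module stays usable at small training resolutions
            r = min(br.r, h, w)
            if r == br.r:
                f = br(x)
            else:
                y = ag.adaptive_avg_pool(x, (r, r))
                y = br.efe(br.extract(br.reduce(y)))
                f = ag.upsample_bilinear(y, (h, w))
            outs.append(ag.narrow(weights, 1, i + 1, 1) * f)
        return self.fuse(ag.concat(outs, axis=1))


# ----------------------------------------------------- spec-level operations
def efe_forward(f_in, module: EFE | None = None) -> Tensor:
    f_in = _to_tensor(f_in)
    if module is None:
        module = EFE(f_in.shape[1])
    return module(f_in)


def edge_branch_forward(x, r: int, cfg: DMAEConfig,
                        module: EdgeBranch | None = None) -> Tensor:
    x = _to_tensor(x)
    if r not in cfg.feat_rls:
        raise ValueError(f"resolution {r} not in feat_rls {cfg.feat_rls}")
    if module is None:
        module = EdgeBranch(cfg.in_channels, cfg.in_channels // cfg.reduction, r)
    return module(x)


def cwg_forward(x, cfg: DMAEConfig, module: CWG | None = None) -> BranchWeights:
    x = _to_tensor(x)
    if module is None:
        module = CWG(cfg.in_channels, cfg.n + 1)
    w = module(x).data.reshape(x.shape[0], cfg.n + 1)
    return BranchWeights(w_local=w[:, 0], w_edge=w[:, 1:])


def dmae_forward(x, cfg: DMAEConfig, module: DMAE | None = None) -> Tensor:
    x = _to_tensor(x)
    if module is None:
        module = DMAE(cfg)
    return module(x)
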