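"""A small reverse-mode automatic differentiation engine on NumPy arrays.

Implements exactly the operator set the detector needs: broadcast
arithmetic, batched matmul, 2-D convolution with groups (hence depthwise),
local/adaptive average pooling, max pooling, nearest and bilinear
resampling, batch/layer normalization, softmax and the usual pointwise
nonlinearities.  Tensors are NCHW; gradients are accumulated through a
topologically sorted backward pass.

The engine is deliberately minimal: no views sharing storage, no in-place
ops, no dtype promotion games.  float32 is the working precision; tests
that need tight finite-difference checks pass float64 arrays in.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(-self, _as_tensor(other))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, 1.0 / float(other))
        return mul(self, reciprocal(_as_tensor(other)))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum-reduce grad down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ------------------------------------------------------------------ pointwise
def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    def backward(g):
        a._accumulate(g * s)

    return _make(a.data * s, (a,), backward)


def reciprocal(a: Tensor) -> Tensor:
    inv = 1.0 / a.data

    def backward(g):
        a._accumulate(-g * inv * inv)

    return _make(inv, (a,), backward)


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)

    def backward(g):
        a._accumulate(g * e)

    return _make(e, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def _sigmoid_stable(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = _sigmoid_stable(a.data)

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def silu(a: Tensor) -> Tensor:
    s = _sigmoid_stable(a.data)
    y = a.data * s

    def backward(g):
        a._accumulate(g * (s + y * (1.0 - s)))

    return _make(y, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


_GELU_C = 0.7978845608028654  # sqrt(2/pi)


def gelu(a: Tensor) -> Tensor:
    # tanh approximation of the Gaussian error linear unit
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    y = 0.5 * x * (1.0 + t)

    def backward(g):
        dt = (1.0 - t * t) * _GELU_C * (1.0 + 3 * 0.044715 * x * x)
        a._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

    return _make(y, (a,), backward)


# ------------------------------------------------------------------ structure
def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        full = np.zeros_like(a.data)
        full[sl] = g
        a._accumulate(full)

    return _make(a.data[sl], (a,), backward)


def chunk(a: Tensor, n: int, axis: int):
    size = a.shape[axis] // n
    return [narrow(a, axis, i * size, size) for i in range(n)]


def reduce_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def reduce_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul_scalar(reduce_sum(a, axis, keepdims), 1.0 / n)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    return _make(y, (a,), backward)


# -------------------------------------------------------------- convolutions
def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """xp: padded (N, C, Hp, Wp) -> windows (N, C, kh, kw, Ho, Wo) view."""
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    sn, sc, sy, sx = xp.strides
    shape = (n, c, kh, kw, ho, wo)
    strides = (sn, sc, sy, sx, sy * sh, sx * sw)
    return np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)


def _col2im(cols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw):
    """cols: (N, C, kh, kw, Ho, Wo) -> gradient w.r.t. unpadded x."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * ph, w + 2 * pw
    ho, wo = cols.shape[4], cols.shape[5]
    gx = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += cols[:, :, i, j]
    return gx[:, :, ph : ph + h, pw : pw + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """w: (Co, Ci/groups, kh, kw); x: (N, Ci, H, W)."""
    n, ci, h, wd = x.shape
    co, cig, kh, kw = w.shape
    if ci != cig * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {ci} channels, weight expects "
            f"{cig * groups} (groups={groups})")
    sh = sw = stride
    ph = pw = padding
    dtype = x.data.dtype

    if kh == 1 and kw == 1 and stride == 1 and padding == 0 and groups == 1:
        # fast path: pointwise conv is a plain matmul
        xm = x.data.reshape(n, ci, h * wd)
        wm = w.data.reshape(co, ci)
        out = np.einsum("oc,ncl->nol", wm, xm, optimize=True).reshape(n, co, h, wd)
        if b is not None:
            out = out + b.data.reshape(1, co, 1, 1)

        def backward_pw(g):
            gm = g.reshape(n, co, h * wd)
            if w.requires_grad:
                gw = np.einsum("nol,ncl->oc", gm, xm, optimize=True)
                w._accumulate(gw.reshape(w.shape).astype(w.data.dtype))
            if b is not None and b.requires_grad:
                b._accumulate(gm.sum(axis=(0, 2)).astype(b.data.dtype))
            if x.requires_grad:
                gx = np.einsum("oc,nol->ncl", wm, gm, optimize=True)
                x._accumulate(gx.reshape(x.shape).astype(dtype))

        parents = (x, w) if b is None else (x, w, b)
        out_t = _make(out, parents, backward_pw)
        _count_conv_flops(out.shape, cig, kh, kw)
        return out_t

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = _im2col(xp, kh, kw, sh, sw)  # (N, Ci, kh, kw, Ho, Wo)
    ho, wo = win.shape[4], win.shape[5]
    l = ho * wo
    # (N, G, Cig*kh*kw, L)
    cols = np.ascontiguousarray(win).reshape(n, groups, cig * kh * kw, l)
    wg = w.data.reshape(groups, co // groups, cig * kh * kw)
    out = np.matmul(wg, cols)  # (N, G, Co/G, L)
    out = out.reshape(n, co, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    def backward(g):
        gm = g.reshape(n, groups, co // groups, l)
        if w.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", gm, cols, optimize=True)
            w._accumulate(gw.reshape(w.shape).astype(w.data.dtype))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)).astype(b.data.dtype))
        if x.requires_grad:
            gcols = np.matmul(np.swapaxes(wg, -1, -2), gm)  # (N,G,K,L)
            gcols = gcols.reshape(n, ci, kh, kw, ho, wo)
            x._accumulate(_col2im(gcols, x.shape, kh, kw, sh, sw, ph, pw).astype(dtype))

    parents = (x, w) if b is None else (x, w, b)
    out_t = _make(out, parents, backward)
    _count_conv_flops(out.shape, cig, kh, kw)
    return out_t


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (..., in), w: (out, in)."""
    out = matmul(x, transpose(w, (1, 0)))
    if b is not None:
        out = add(out, b)
    _count_linear_flops(x.shape, w.shape)
    return out


# ----------------------------------------------------------------- pooling
def local_avg_pool(x: Tensor, k: int = 3) -> Tensor:
    """k x k mean, stride 1, same padding; the divisor counts only valid
    (in-image) cells, so a spatially constant map is reproduced exactly,
    borders included."""
    n, c, h, w = x.shape
    p = k // 2
    ones = np.ones((1, 1, h, w), dtype=x.data.dtype)
    count = _window_sum(ones, k, p)  # (1,1,H,W) valid-cell counts
    s = _window_sum(x.data, k, p)
    y = s / count

    def backward(g):
        x._accumulate(_window_sum(g / count, k, p).astype(x.data.dtype))

    return _make(y, (x,), backward)


def _window_sum(a: np.ndarray, k: int, p: int) -> np.ndarray:
    n, c, h, w = a.shape
    ap = np.pad(a, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros_like(a)
    for i in range(k):
        for j in range(k):
            out += ap[:, :, i : i + h, j : j + w]
    return out


def max_pool(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    n, c, h, w = x.shape
    neg = np.finfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    win = _im2col(xp, k, k, stride, stride)  # (N,C,k,k,Ho,Wo)
    ho, wo = win.shape[4], win.shape[5]
    flat = np.ascontiguousarray(win).reshape(n, c, k * k, ho, wo)
    idx = flat.argmax(axis=2)  # (N,C,Ho,Wo)
    y = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gcols = np.zeros_like(flat)
        np.put_along_axis(gcols, idx[:, :, None], g[:, :, None], axis=2)
        gcols = gcols.reshape(n, c, k, k, ho, wo)
        x._accumulate(_col2im(gcols, x.shape, k, k, stride, stride, padding, padding))

    return _make(y, (x,), backward)


def _adaptive_edges(in_size: int, out_size: int):
    starts = (np.arange(out_size) * in_size) // out_size
    ends = -((-(np.arange(out_size) + 1) * in_size) // out_size)  # ceil
    return starts, ends


def adaptive_avg_pool(x: Tensor, out_hw) -> Tensor:
    """Adaptive average pooling with floor/ceil window partitioning
    (exact-divisor cases reduce to disjoint block means)."""
    oh, ow = out_hw
    n, c, h, w = x.shape
    if oh > h or ow > w:
        raise ValueError(
            f"adaptive_avg_pool target {oh}x{ow} exceeds input {h}x{w}")
    hs, he = _adaptive_edges(h, oh)
    ws, we = _adaptive_edges(w, ow)
    y = np.empty((n, c, oh, ow), dtype=x.data.dtype)
    for i in range(oh):
        for j in range(ow):
            y[:, :, i, j] = x.data[:, :, hs[i]:he[i], ws[j]:we[j]].mean(axis=(2, 3))

    def backward(g):
        gx = np.zeros_like(x.data)
        for i in range(oh):
            for j in range(ow):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                gx[:, :, hs[i]:he[i], ws[j]:we[j]] += g[:, :, i, j, None, None] / area
        x._accumulate(gx)

    return _make(y, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        gr = g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accumulate(gr)

    return _make(y, (x,), backward)


def _bilinear_matrix(in_size: int, out_size: int, dtype) -> np.ndarray:
    """Row-stochastic (out, in) interpolation matrix, half-pixel convention."""
    a = np.zeros((out_size, in_size), dtype=dtype)
    if in_size == 1:
        a[:, 0] = 1.0
        return a
    scale = in_size / out_size
    src = (np.arange(out_size) + 0.5) * scale - 0.5
    src = np.clip(src, 0, in_size - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = src - lo
    a[np.arange(out_size), lo] += 1.0 - frac
    a[np.arange(out_size), hi] += frac
    return a


def upsample_bilinear(x: Tensor, out_hw) -> Tensor:
    oh, ow = out_hw
    n, c, h, w = x.shape
    ah = _bilinear_matrix(h, oh, x.data.dtype)
    aw = _bilinear_matrix(w, ow, x.data.dtype)
    y = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)

    def backward(g):
        gx = np.einsum("oh,ncop,pw->nchw", ah, g, aw, optimize=True)
        x._accumulate(gx.astype(x.data.dtype))

    return _make(y, (x,), backward)


# ------------------------------------------------------------- normalization
def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, axis: int, eps: float = 1e-5) -> Tensor:
    """Normalize along one axis; gamma/beta broadcast along that axis."""
    mu = x.data.mean(axis=axis, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axis, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    shape = [1] * x.ndim
    shape[axis] = x.shape[axis]
    gb = gamma.data.reshape(shape)
    bb = beta.data.reshape(shape)
    y = xhat * gb + bb
    m = x.shape[axis]

    def backward(g):
        if gamma.requires_grad:
            axes = tuple(i for i in range(x.ndim) if i != (axis % x.ndim))
            gamma._accumulate((g * xhat).sum(axis=axes).astype(gamma.data.dtype))
        if beta.requires_grad:
            axes = tuple(i for i in range(x.ndim) if i != (axis % x.ndim))
            beta._accumulate(g.sum(axis=axes).astype(beta.data.dtype))
        if x.requires_grad:
            gh = g * gb
            t1 = gh.sum(axis=axis, keepdims=True)
            t2 = (gh * xhat).sum(axis=axis, keepdims=True)
            gx = (inv / m) * (m * gh - t1 - xhat * t2)
            x._accumulate(gx.astype(x.data.dtype))

    return _make(y, (x, gamma, beta), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.03,
               eps: float = 1e-3) -> Tensor:
    """2-D batch normalization over (N, H, W) per channel."""
    n, c, h, w = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    y = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
    m = n * h * w

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)).astype(gamma.data.dtype))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)).astype(beta.data.dtype))
        if x.requires_grad:
            gh = g * gamma.data[None, :, None, None]
            if training:
                t1 = gh.sum(axis=(0, 2, 3), keepdims=True)
                t2 = (gh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv[None, :, None, None] / m) * (m * gh - t1 - xhat * t2)
            else:
                gx = gh * inv[None, :, None, None]
            x._accumulate(gx.astype(x.data.dtype))

    return _make(y, (x, gamma, beta), backward)


# ------------------------------------------------------------------- losses
def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable elementwise binary cross-entropy, mean-reduced."""
    z = logits.data
    t = np.asarray(targets, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g * (s - t) / n)

    return _make(loss.mean(), (logits,), backward)


def abs_val(a: Tensor) -> Tensor:
    s = np.sign(a.data)

    def backward(g):
        a._accumulate(g * s)

    return _make(np.abs(a.data), (a,), backward)


# -------------------------------------------------------------- FLOP counter
class FlopCounter:
    """Counts 2-FLOPs-per-MAC for parameterized conv and linear layers seen
    during a forward pass.  Parameter-free ops (pooling, resampling,
    activations, normalization statistics) and data-dependent attention
    matmuls are excluded; conv + batch-norm pairs therefore count as fused.
    """

    _active: list["FlopCounter"] = []

    def __init__(self):
        self.flops = 0

    def __enter__(self):
        FlopCounter._active.append(self)
        return self

    def __exit__(self, *exc):
        FlopCounter._active.pop()
        return False


def _count_conv_flops(out_shape, cig, kh, kw):
    if FlopCounter._active:
        n, co, ho, wo = out_shape
        FlopCounter._active[-1].flops += 2 * n * co * ho * wo * cig * kh * kw


def _count_linear_flops(x_shape, w_shape):
    if FlopCounter._active:
        tokens = int(np.prod(x_shape[:-1]))
        out_f, in_f = w_shape
        FlopCounter._active[-1].flops += 2 * tokens * in_f * out_f
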