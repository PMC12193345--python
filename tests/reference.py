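"""Independent loop-based reference implementations used as oracles.

Everything here is written with explicit Python loops over output cells,
deliberately sharing no code with the package's vectorized forward path.
Inputs are small (<= 8x8x8), so quadratic slowness is fine.
"""

import numpy as np


def conv2d_ref(x, w, b=None, stride=1, padding=0, groups=1):
    n, ci, h, wd = x.shape
    co, cig, kh, kw = w.shape
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    cog = co // groups
    out = np.zeros((n, co, ho, wo), dtype=np.float64)
    for b_i in range(n):
        for o in range(co):
            g = o // cog
            for oy in range(ho):
                for ox in range(wo):
                    acc = 0.0
                    for c in range(cig):
                        ci_abs = g * cig + c
                        for ky in range(kh):
                            for kx in range(kw):
                                iy = oy * stride + ky - padding
                                ix = ox * stride + kx - padding
                                if 0 <= iy < h and 0 <= ix < wd:
                                    acc += x[b_i, ci_abs, iy, ix] * w[o, c, ky, kx]
                    if b is not None:
                        acc += b[o]
                    out[b_i, o, oy, ox] = acc
    return out


def local_mean_ref(x, k=3):
    """k x k windowed mean, stride 1, same size, divisor = valid cells only."""
    n, c, h, w = x.shape
    p = k // 2
    out = np.zeros_like(x, dtype=np.float64)
    for b in range(n):
        for ch in range(c):
            for y in range(h):
                for xx in range(w):
                    acc, cnt = 0.0, 0
                    for dy in range(-p, p + 1):
                        for dx in range(-p, p + 1):
                            yy, xc = y + dy, xx + dx
                            if 0 <= yy < h and 0 <= xc < w:
                                acc += x[b, ch, yy, xc]
                                cnt += 1
                    out[b, ch, y, xx] = acc / cnt
    return out


def layer_norm_channel_ref(x, gamma, beta, eps=1e-5):
    """Channel-axis layer norm at every spatial position of an NCHW map."""
    n, c, h, w = x.shape
    out = np.zeros_like(x, dtype=np.float64)
    for b in range(n):
        for y in range(h):
            for xx in range(w):
                v = x[b, :, y, xx]
                mu = v.mean()
                var = ((v - mu) ** 2).mean()
                out[b, :, y, xx] = (v - mu) / np.sqrt(var + eps) * gamma + beta
    return out


def gelu_ref(x):
    c = np.sqrt(2.0 / np.pi)
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x**3)))


def silu_ref(x):
    return x / (1.0 + np.exp(-x))


def sigmoid_ref(x):
    return 1.0 / (1.0 + np.exp(-x))


def bn_eval_ref(x, gamma, beta, mean, var, eps=1e-3):
    return ((x - mean[None, :, None, None]) / np.sqrt(var[None, :, None, None] + eps)
            * gamma[None, :, None, None] + beta[None, :, None, None])


def conv_bn_act_ref(x, mod, act=True):
    """Eval-mode forward of a ConvBNAct module, by loops."""
    y = conv2d_ref(x, mod.conv.weight.data, None, mod.conv.s, mod.conv.p, mod.conv.g)
    y = bn_eval_ref(y, mod.bn.gamma.data, mod.bn.beta.data,
                    mod.bn.running_mean, mod.bn.running_var, mod.bn.eps)
    return silu_ref(y) if (act and mod.act) else y


def dsconv_ref(x, mod):
    y = conv2d_ref(x, mod.dw.weight.data,
                   None if mod.dw.bias is None else mod.dw.bias.data,
                   mod.dw.s, mod.dw.p, mod.dw.g)
    return conv2d_ref(y, mod.pw.weight.data,
                      None if mod.pw.bias is None else mod.pw.bias.data, 1, 0, 1)


def poolformer_ref(x, block):
    """Step-by-step PoolFormer block: LN -> windowed mean minus input ->
    residual; LN -> two pointwise layers with GELU -> residual."""
    t = layer_norm_channel_ref(x, block.norm1.gamma.data, block.norm1.beta.data)
    y = x + (local_mean_ref(t) - t)
    t2 = layer_norm_channel_ref(y, block.norm2.gamma.data, block.norm2.beta.data)
    hidden = gelu_ref(conv2d_ref(t2, block.fc1.weight.data, block.fc1.bias.data))
    out = conv2d_ref(hidden, block.fc2.weight.data, block.fc2.bias.data)
    return y + out


def adaptive_pool_ref(x, r):
    n, c, h, w = x.shape
    out = np.zeros((n, c, r, r), dtype=np.float64)
    for i in range(r):
        y0, y1 = (i * h) // r, -((-(i + 1) * h) // r)
        for j in range(r):
            x0, x1 = (j * w) // r, -((-(j + 1) * w) // r)
            out[:, :, i, j] = x[:, :, y0:y1, x0:x1].mean(axis=(2, 3))
    return out


def bilinear_ref(x, oh, ow):
    """Half-pixel-aligned bilinear resize by per-output-pixel gathering."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, oh, ow), dtype=np.float64)
    for oy in range(oh):
        sy = min(max((oy + 0.5) * h / oh - 0.5, 0), h - 1)
        y0 = int(np.floor(sy)); y1 = min(y0 + 1, h - 1); fy = sy - y0
        for ox in range(ow):
            sx = min(max((ox + 0.5) * w / ow - 0.5, 0), w - 1)
            x0 = int(np.floor(sx)); x1 = min(x0 + 1, w - 1); fx = sx - x0
            out[:, :, oy, ox] = ((1 - fy) * (1 - fx) * x[:, :, y0, x0]
                                 + (1 - fy) * fx * x[:, :, y0, x1]
                                 + fy * (1 - fx) * x[:, :, y1, x0]
                                 + fy * fx * x[:, :, y1, x1])
    return out


def efe_ref(x, efe):
    edge = x - local_mean_ref(x)
    return x + sigmoid_ref(dsconv_ref(edge, efe.ds))


def edge_branch_ref(x, br):
    n, c, h, w = x.shape
    y = adaptive_pool_ref(x, br.r)
    y = conv_bn_act_ref(y, br.reduce)
    y = dsconv_ref(y, br.extract)
    y = efe_ref(y, br.efe)
    return bilinear_ref(y, h, w)


def cwg_ref(x, cwg):
    g = x.mean(axis=(2, 3), keepdims=True)
    hdn = np.maximum(conv2d_ref(g, cwg.fc1.weight.data, cwg.fc1.bias.data), 0)
    return sigmoid_ref(conv2d_ref(hdn, cwg.fc2.weight.data, cwg.fc2.bias.data))


def dmae_ref(x, dmae):
    """Full weighted multi-branch composition, step by step."""
    weights = cwg_ref(x, dmae.cwg)  # (n, n_branches+1, 1, 1)
    parts = [weights[:, 0:1] * dsconv_ref(x, dmae.local)]
    for i, br in enumerate(dmae.branches):
        parts.append(weights[:, i + 1:i + 2] * edge_branch_ref(x, br))
    cat = np.concatenate(parts, axis=1)
    return conv_bn_act_ref(cat, dmae.fuse)


# --------------------------------------------------------------- evaluation
def ap_envelope_ref(flags, n_gt):
    """All-point AP by direct summation over the sorted detection list."""
    tp = fp = 0
    points = []
    for f in flags:
        tp += int(f)
        fp += int(not f)
        points.append((tp / n_gt, tp / (tp + fp)))
    ap, r_prev = 0.0, 0.0
    for i, (r, _) in enumerate(points):
        if flags[i]:
            p_max = max(p for rr, p in points if rr >= r)
            ap += (r - r_prev) * p_max
            r_prev = r
    return ap


def ap_grid_ref(flags, n_gt):
    """101-point AP: mean of the precision envelope on recalls 0..1."""
    tp = fp = 0
    points = []
    for f in flags:
        tp += int(f)
        fp += int(not f)
        points.append((tp / n_gt, tp / (tp + fp)))
    vals = []
    for r in np.linspace(0, 1, 101):
        cand = [p for rr, p in points if rr >= r - 1e-12]
        vals.append(max(cand) if cand else 0.0)
    return float(np.mean(vals))


def iou_ref(a, b):
    """IoU of two (cx, cy, w, h) boxes via corner arithmetic."""
    ax1, ay1 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax2, ay2 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx2, by2 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    return inter / (a[2] * a[3] + b[2] * b[3] - inter) if inter else 0.0


def evaluate_ref(dets_by_img, gts_by_img, num_classes, thresholds):
    """Brute-force per-class AP at each threshold (grid101), plus flags."""
    out = {}
    for c in range(num_classes):
        n_gt = sum(sum(1 for g in gs if g[0] == c) for gs in gts_by_img.values())
        if n_gt == 0:
            continue
        per_thr = []
        for thr in thresholds:
            records = []
            for img, dets in dets_by_img.items():
                cd = sorted([d for d in dets if d[0] == c], key=lambda d: -d[5])
                gts = [g for g in gts_by_img.get(img, []) if g[0] == c]
                used = [False] * len(gts)
                for d in cd:
                    best, best_iou = -1, 0.0
                    for j, g in enumerate(gts):
                        if not used[j]:
                            i = iou_ref(d[1:5], g[1:5])
                            if i > best_iou:
                                best, best_iou = j, i
                    ok = best >= 0 and best_iou >= thr
                    if ok:
                        used[best] = True
                    records.append((d[5], ok, img))
            records.sort(key=lambda r: (-r[0], r[2]))
            per_thr.append(ap_grid_ref([r[1] for r in records], n_gt))
        out[c] = per_thr
    return out
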