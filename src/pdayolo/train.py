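"""Training loop and loss plumbing.

The loss is deliberately plain detector plumbing (the architecture work
lives in the blocks, not here): each ground-truth box is assigned to the
cell containing its center at one scale chosen by box size; positives get
a one-hot class target and a target distance quadruple (left/top/right/
bottom from the cell center, in stride units); the loss is mean binary
cross-entropy over all class logits plus an L1 penalty between the
DFL-expected distances and the targets at positive cells, optimized with
SGD (momentum + weight decay).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .nn import SGD
from .nn import autograd as ag
from .model import REG_MAX, STRIDES, DetectionModel, TrainConfig
from .predict import load_image
from .synth import read_yolo_labels


class DataError(ValueError):
    pass


@dataclass
class TrainLog:
    config: dict
    epoch_loss: list[float] = field(default_factory=list)


def load_manifest(path) -> dict:
    path = Path(path)
    man = yaml.safe_load(path.read_text())
    root = Path(man.get("path", path.parent))
    if not root.is_absolute():
        root = path.parent / root
    return {"root": root, "train": man["train"], "val": man.get("val"),
            "test": man.get("test"), "names": man.get("names", [])}


def load_split(manifest: dict, split: str, image_size: int, num_classes: int):
    """-> (images (n,3,s,s), labels list of (k,5) arrays [cls cx cy w h])."""
    img_dir = manifest["root"] / manifest[split]
    files = sorted(p for p in img_dir.glob("*") if p.suffix.lower() in
                   (".png", ".jpg", ".jpeg"))
    if not files:
        raise DataError(f"empty {split} split: no images under {img_dir}")
    images, labels = [], []
    for f in files:
        images.append(load_image(f, image_size))
        lbl = Path(str(f.parent).replace("images", "labels")) / (f.stem + ".txt")
        anns = read_yolo_labels(lbl) if lbl.exists() else []
        arr = np.array([[a.class_id, a.cx, a.cy, a.w, a.h] for a in anns],
                       dtype=np.float32).reshape(-1, 5)
        if arr.size and arr[:, 0].max() >= num_classes:
            raise DataError(f"class index {int(arr[:, 0].max())} >= "
                            f"{num_classes} in {lbl}")
        labels.append(arr)
    return np.stack(images), labels


def _scale_for_box(w: float, h: float, image_size: int) -> int:
    size = max(w, h) * image_size
    if size < 8 * REG_MAX / 2:       # fits the stride-8 regression range
        return 0
    if size < 16 * REG_MAX / 2:
        return 1
    return 2


def detection_loss(outputs, labels, image_size: int, num_classes: int,
                   box_weight: float = 0.5):
    """outputs: per-scale (box_logits, cls_logits) tensors for a batch."""
    n = outputs[0][0].shape[0]
    total = None
    bins = ag.Tensor(np.arange(REG_MAX, dtype=np.float32).reshape(1, 1, REG_MAX, 1, 1))
    for si, (box_t, cls_t) in enumerate(outputs):
        _, _, h, w = cls_t.shape
        cls_target = np.zeros(cls_t.shape, dtype=np.float32)
        dist_target = np.zeros((n, 4, h, w), dtype=np.float32)
        pos = np.zeros((n, 1, h, w), dtype=np.float32)
        for b in range(n):
            for cid, cx, cy, bw, bh in labels[b]:
                if _scale_for_box(bw, bh, image_size) != si:
                    continue
                ix = min(int(cx * w), w - 1)
                iy = min(int(cy * h), h - 1)
                cls_target[b, int(cid), iy, ix] = 1.0
                x1, y1 = (cx - bw / 2) * w, (cy - bh / 2) * h
                x2, y2 = (cx + bw / 2) * w, (cy + bh / 2) * h
                d = np.array([ix + 0.5 - x1, iy + 0.5 - y1,
                              x2 - ix - 0.5, y2 - iy - 0.5])
                dist_target[b, :, iy, ix] = np.clip(d, 0.0, REG_MAX - 1.01)
                pos[b, 0, iy, ix] = 1.0
        loss = ag.bce_with_logits(cls_t, cls_target)
        npos = pos.sum()
        if npos > 0:
            dist = ag.softmax(box_t.reshape(n, 4, REG_MAX, h, w), axis=2)
            dist = (dist * bins).sum(axis=2)  # (n,4,h,w) expected distances
            diff = ag.abs_val((dist - ag.Tensor(dist_target)) * ag.Tensor(pos))
            loss = loss + diff.sum() * (box_weight / (4.0 * npos))
        total = loss if total is None else total + loss
    return total


def train_model(model: DetectionModel, data_manifest, cfg: TrainConfig | None = None):
    """Train in place; returns (model, TrainLog)."""
    cfg = cfg or TrainConfig()
    if cfg.optimizer.upper() != "SGD":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    manifest = load_manifest(data_manifest)
    images, labels = load_split(manifest, "train", cfg.image_size,
                                model.num_classes)
    log = TrainLog(config=cfg.as_dict())
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = len(images)
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            outputs = model(ag.Tensor(images[idx]))
            loss = detection_loss(outputs, [labels[i] for i in idx],
                                  cfg.image_size, model.num_classes)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            nb += 1
        log.epoch_loss.append(epoch_loss / nb)
    model.eval()
    return model, log
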