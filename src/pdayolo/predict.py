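"""Inference: decode raw head outputs into boxes and run non-maximum
suppression.  The head regresses, per anchor cell, four distance
distributions over 16 bins; the decoded distance is the softmax
expectation, in units of the scale's stride, measured from the cell
center.  Class confidences are independent sigmoids.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .model import REG_MAX, STRIDES, DetectionModel
from .nn.autograd import _sigmoid_stable


@dataclass
class Detection:
    """A predicted box in normalized image coordinates (center/size)."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float

    def xyxy(self, width: float = 1.0, height: float = 1.0):
        x1 = (self.cx - self.w / 2) * width
        y1 = (self.cy - self.h / 2) * height
        x2 = (self.cx + self.w / 2) * width
        y2 = (self.cy + self.h / 2) * height
        return x1, y1, x2, y2


def _softmax(x, axis):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def decode_outputs(outputs, input_size: int, conf_threshold: float):
    """Raw per-scale (box_logits, cls_logits) -> candidate arrays
    (boxes_xyxy normalized, scores, class_ids)."""
    boxes, scores, classes = [], [], []
    for (box_t, cls_t), stride in zip(outputs, STRIDES):
        box = box_t.data if hasattr(box_t, "data") else box_t
        cls = cls_t.data if hasattr(cls_t, "data") else cls_t
        n, _, h, w = box.shape
        assert n == 1, "decode handles one image at a time"
        dist = _softmax(box.reshape(4, REG_MAX, h, w), axis=1)
        dist = (dist * np.arange(REG_MAX)[None, :, None, None]).sum(axis=1)  # (4,h,w)
        gx, gy = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
        x1 = (gx - dist[0]) * stride
        y1 = (gy - dist[1]) * stride
        x2 = (gx + dist[2]) * stride
        y2 = (gy + dist[3]) * stride
        conf = _sigmoid_stable(cls[0])  # (nc,h,w)
        cid = conf.argmax(axis=0)
        cmax = conf.max(axis=0)
        keep = cmax >= conf_threshold
        if not keep.any():
            continue
        bx = np.stack([x1, y1, x2, y2], axis=-1)[keep] / input_size
        boxes.append(np.clip(bx, 0.0, 1.0))
        scores.append(cmax[keep])
        classes.append(cid[keep])
    if not boxes:
        return (np.zeros((0, 4)), np.zeros(0), np.zeros(0, dtype=int))
    return np.concatenate(boxes), np.concatenate(scores), np.concatenate(classes)


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n,4) and (m,4) xyxy boxes."""
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy suppression keeping the higher-confidence box."""
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        ious = box_iou_xyxy(boxes[i:i + 1], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_threshold]
    return keep


def predict(model: DetectionModel, image, conf_threshold: float = 0.25,
            iou_threshold: float = 0.45, input_size: int = 640) -> list[Detection]:
    """Run the detector on one image (path, PIL image or HxWx3 array)."""
    if not 0.0 <= conf_threshold <= 1.0 or not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    arr = load_image(image, input_size)
    model.eval()
    outputs = model(arr[None])
    boxes, scores, classes = decode_outputs(outputs, input_size, conf_threshold)
    dets: list[Detection] = []
    for c in np.unique(classes):
        m = classes == c
        for i in nms(boxes[m], scores[m], iou_threshold):
            x1, y1, x2, y2 = boxes[m][i]
            if x2 <= x1 or y2 <= y1:
                continue
            dets.append(Detection(int(c), (x1 + x2) / 2, (y1 + y2) / 2,
                                  x2 - x1, y2 - y1, float(scores[m][i])))
    dets.sort(key=lambda d: -d.confidence)
    return dets


def predict_timed(model, image, **kw):
    """predict() plus the forward+decode+NMS wall time in milliseconds."""
    arr = load_image(image, kw.get("input_size", 640))
    t0 = time.perf_counter()
    dets = predict(model, arr, **kw)
    return dets, (time.perf_counter() - t0) * 1e3


def load_image(image, input_size: int) -> np.ndarray:
    """-> (3, s, s) float array in [0, 1]."""
    if isinstance(image, np.ndarray):
        arr = image
        if arr.ndim == 3 and arr.shape[0] == 3 and arr.shape[1] == input_size:
            return arr.astype(np.float32)
    else:
        try:
            arr = np.asarray(Image.open(image).convert("RGB"))
        except OSError as err:
            raise IOError(f"cannot read image {image!r}: {err}") from err
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"expected an RGB image, got shape {arr.shape}")
    img = Image.fromarray(arr.astype(np.uint8)).resize((input_size, input_size),
                                                       Image.BILINEAR)
    out = np.asarray(img, dtype=np.float32) / 255.0
    return out.transpose(2, 0, 1)
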