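"""Detection evaluation: IoU matching, precision/recall/F1, average
precision, mAP@0.5 and mAP@0.5:0.95, mean detection time.

Definitions follow the standard detection protocol:

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R)
    AP = integral of the precision-recall curve, per class
    mAP = unweighted mean of per-class APs; mAP@0.5:0.95 additionally
    averages over IoU thresholds 0.50, 0.55, ..., 0.95.

Matching is greedy and class-wise: detections sorted by descending
confidence each claim the highest-IoU unmatched ground truth if that IoU
reaches the threshold; every ground truth is used at most once.  AP is
integrated on a 101-point recall grid by default (the convention matching
mAP@0.5:0.95 usage); the all-point precision-envelope integral is
available via ``interpolation="envelope"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IOU_THRESHOLDS = np.round(np.arange(0.5, 0.96, 0.05), 2)
MIN_CONFIDENCE = 0.001


@dataclass
class EvalCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0


@dataclass
class EvalSummary:
    per_class_ap50: dict
    per_class_ap50_95: dict
    map50: float
    map50_95: float
    precision: float
    recall: float
    f1: float
    mean_detection_time_ms: float | None = None
    skipped_classes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_class_AP50": self.per_class_ap50,
            "per_class_AP50_95": self.per_class_ap50_95,
            "mAP50": self.map50, "mAP50_95": self.map50_95,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "mean_detection_time_ms": self.mean_detection_time_ms,
        }


def box_iou(a, b) -> float:
    """IoU of two boxes given as (cx, cy, w, h), any consistent units."""
    ax1, ay1, ax2, ay2 = a[0] - a[2] / 2, a[1] - a[3] / 2, a[0] + a[2] / 2, a[1] + a[3] / 2
    bx1, by1, bx2, by2 = b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return float(inter / union)


def match_detections(dets, gts, iou_thr: float):
    """Greedy one-to-one matching for a single class.

    ``dets``: (cx, cy, w, h, confidence) rows sorted by descending
    confidence (re-sorted defensively); ``gts``: (cx, cy, w, h) rows.
    Returns (EvalCounts, per-detection TP flags aligned with the sorted
    order).
    """
    dets = sorted(dets, key=lambda d: -d[4])
    used = [False] * len(gts)
    flags = []
    for d in dets:
        best, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if used[j]:
                continue
            iou = box_iou(d[:4], g[:4])
            if iou > best_iou:
                best, best_iou = j, iou
        if best >= 0 and best_iou >= iou_thr:
            used[best] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    return EvalCounts(TP=tp, FP=len(flags) - tp, FN=len(gts) - tp), flags


def precision_recall_f1(c: EvalCounts):
    p = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else 0.0
    r = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return p, r, f1


def average_precision(flags, confidences, n_gt: int,
                      interpolation: str = "grid101") -> float:
    """AP from per-detection TP flags and confidences.

    ``grid101`` samples the precision envelope on recalls 0, 0.01, ..., 1;
    ``envelope`` integrates the all-point precision envelope exactly.
    """
    if n_gt < 1:
        raise ValueError("average_precision requires at least one ground truth")
    if len(flags) == 0:
        return 0.0
    order = np.argsort(-np.asarray(confidences, dtype=float), kind="stable")
    tp = np.asarray(flags, dtype=float)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # precision envelope: best precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "grid101":
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(recall, grid, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(vals.mean())
    if interpolation == "envelope":
        r_prev, ap = 0.0, 0.0
        for i in range(len(recall)):
            if tp[i]:
                ap += (recall[i] - r_prev) * env[i]
                r_prev = recall[i]
        return float(ap)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_ap(per_class_aps: dict) -> float:
    if not per_class_aps:
        raise ValueError("no classes to average")
    return float(np.mean(list(per_class_aps.values())))


def mean_detection_time(times_ms) -> float:
    times_ms = list(times_ms)
    if not times_ms:
        raise ValueError("mean_detection_time requires at least one value")
    return float(np.mean(times_ms))


def evaluate(detections_by_image: dict, gts_by_image: dict, num_classes: int,
             interpolation: str = "grid101",
             times_ms=None) -> EvalSummary:
    """Full evaluation over a set of images.

    ``detections_by_image``: image id -> list of (class_id, cx, cy, w, h,
    conf); ``gts_by_image``: image id -> list of (class_id, cx, cy, w, h).
    """
    image_ids = sorted(set(detections_by_image) | set(gts_by_image))
    ap50, ap50_95, skipped = {}, {}, []
    counts50 = EvalCounts()
    for c in range(num_classes):
        n_gt = sum(sum(1 for g in gts_by_image.get(i, []) if g[0] == c)
                   for i in image_ids)
        if n_gt == 0:
            skipped.append(c)
            continue
        aps = []
        for thr in IOU_THRESHOLDS:
            flags_all, confs_all = [], []
            for i in image_ids:
                dets = [(d[1], d[2], d[3], d[4], d[5])
                        for d in detections_by_image.get(i, [])
                        if d[0] == c and d[5] >= MIN_CONFIDENCE]
                gts = [(g[1], g[2], g[3], g[4]) for g in gts_by_image.get(i, [])
                       if g[0] == c]
                cnt, flags = match_detections(dets, gts, thr)
                flags_all.extend(flags)
                confs_all.extend(sorted((d[4] for d in dets), reverse=True))
                if thr == IOU_THRESHOLDS[0]:
                    counts50.TP += cnt.TP
                    counts50.FP += cnt.FP
                    counts50.FN += cnt.FN
            aps.append(average_precision(flags_all, confs_all, n_gt, interpolation))
        ap50[c] = aps[0]
        ap50_95[c] = float(np.mean(aps))
    p, r, f1 = precision_recall_f1(counts50)
    return EvalSummary(
        per_class_ap50=ap50, per_class_ap50_95=ap50_95,
        map50=mean_ap(ap50), map50_95=mean_ap(ap50_95),
        precision=p, recall=r, f1=f1,
        mean_detection_time_ms=(mean_detection_time(times_ms)
                                if times_ms else None),
        skipped_classes=skipped)
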