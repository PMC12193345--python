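"""Evaluation metrics: IoU, greedy matching, P/R/F1, AP integration, mAP,
and equivalence with a brute-force reference evaluator."""

import numpy as np
import pytest

from pdayolo.metrics import (IOU_THRESHOLDS, EvalCounts, average_precision,
                             box_iou, evaluate, match_detections, mean_ap,
                             mean_detection_time, precision_recall_f1)

from reference import ap_envelope_ref, ap_grid_ref, evaluate_ref, iou_ref


class TestBoxIoU:
    def test_identical_boxes(self):
        assert box_iou((0.5, 0.5, 0.2, 0.2), (0.5, 0.5, 0.2, 0.2)) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert box_iou((0.1, 0.1, 0.1, 0.1), (0.9, 0.9, 0.1, 0.1)) == 0.0

    def test_corner_overlap_is_one_seventh(self):
        # xyxy (0,0,2,2) vs (1,1,3,3): intersection 1, union 7
        a = (1.0, 1.0, 2.0, 2.0)
        b = (2.0, 2.0, 2.0, 2.0)
        assert box_iou(a, b) == pytest.approx(1 / 7)

    def test_matches_reference_on_random_boxes(self, rng):
        for _ in range(100):
            a = rng.uniform(0.1, 0.9, 2).tolist() + rng.uniform(0.05, 0.4, 2).tolist()
            b = rng.uniform(0.1, 0.9, 2).tolist() + rng.uniform(0.05, 0.4, 2).tolist()
            assert box_iou(a, b) == pytest.approx(iou_ref(a, b))
            assert 0.0 <= box_iou(a, b) <= 1.0


class TestMatching:
    GT = [(0.5, 0.5, 0.2, 0.2)]

    def test_single_match(self):
        dets = [(0.52, 0.5, 0.2, 0.2, 0.9)]  # IoU ~ 0.8
        c, flags = match_detections(dets, self.GT, 0.5)
        assert (c.TP, c.FP, c.FN) == (1, 0, 0) and flags == [True]

    def test_duplicate_detection_counts_one_tp_one_fp(self):
        dets = [(0.5, 0.5, 0.2, 0.2, 0.9), (0.5, 0.5, 0.2, 0.2, 0.8)]
        c, flags = match_detections(dets, self.GT, 0.5)
        assert (c.TP, c.FP, c.FN) == (1, 1, 0) and flags == [True, False]

    def test_below_threshold_is_fp_and_fn(self):
        dets = [(0.62, 0.5, 0.2, 0.2, 0.9)]  # IoU ~ 0.25
        c, flags = match_detections(dets, self.GT, 0.5)
        assert (c.TP, c.FP, c.FN) == (0, 1, 1) and flags == [False]


class TestPrecisionRecallF1:
    def test_symmetric_counts(self):
        assert precision_recall_f1(EvalCounts(8, 2, 2)) == (0.8, 0.8, pytest.approx(0.8))

    def test_harmonic_mean_arithmetic(self):
        p, r, f1 = 0.9, 0.8, 2 * 0.9 * 0.8 / 1.7
        counts = EvalCounts(TP=72, FP=8, FN=18)  # P=0.9, R=0.8
        got = precision_recall_f1(counts)
        assert got[0] == pytest.approx(p) and got[1] == pytest.approx(r)
        assert got[2] == pytest.approx(0.847059, abs=1e-6)

    def test_degenerate_all_zero(self):
        assert precision_recall_f1(EvalCounts(0, 0, 5)) == (0.0, 0.0, 0.0)


class TestAveragePrecision:
    def test_perfect_detector(self):
        flags = [True] * 4
        confs = [0.9, 0.8, 0.7, 0.6]
        assert average_precision(flags, confs, 4, "envelope") == pytest.approx(1.0)
        assert average_precision(flags, confs, 4, "grid101") == pytest.approx(1.0)

    def test_tp_fp_tp_envelope(self):
        ap = average_precision([True, False, True], [0.9, 0.8, 0.7], 2, "envelope")
        assert ap == pytest.approx(0.5 * 1 + 0.5 * (2 / 3), abs=1e-9)

    def test_tp_fp_tp_grid(self):
        ap = average_precision([True, False, True], [0.9, 0.8, 0.7], 2, "grid101")
        assert ap == pytest.approx((51 + 50 * (2 / 3)) / 101, abs=1e-9)

    def test_matches_reference_on_random_flag_sequences(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 12))
            flags = rng.uniform(size=n) > 0.4
            confs = np.sort(rng.uniform(size=n))[::-1]
            n_gt = int(flags.sum() + rng.integers(0, 4))
            if n_gt == 0:
                continue
            assert average_precision(flags, confs, n_gt, "envelope") == \
                pytest.approx(ap_envelope_ref(list(flags), n_gt), abs=1e-9)
            assert average_precision(flags, confs, n_gt, "grid101") == \
                pytest.approx(ap_grid_ref(list(flags), n_gt), abs=1e-9)

    def test_adding_a_tp_never_decreases_ap(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 10))
            flags = list(rng.uniform(size=n) > 0.5)
            confs = list(np.sort(rng.uniform(size=n))[::-1])
            n_gt = sum(flags) + 2
            base = average_precision(flags, confs, n_gt, "envelope")
            for pos, conf in ((0, max(confs) + 1), (len(flags), min(confs) - 1)):
                f2 = flags[:pos] + [True] + flags[pos:]
                c2 = confs[:pos] + [conf] + confs[pos:]
                assert average_precision(f2, c2, n_gt, "envelope") >= base - 1e-12

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError):
            average_precision([True], [0.9], 0)


class TestMeanAP:
    def test_unanimity_and_mean(self):
        assert mean_ap({c: 1.0 for c in range(5)}) == 1.0
        assert mean_ap({0: 0.8, 1: 0.6}) == pytest.approx(0.7)

    def test_full_evaluator_matches_brute_force_reference(self, rng):
        """Randomized small scenes: planted TPs with jitter plus FPs."""
        dets, gts = {}, {}
        for img in range(10):
            gts[img] = []
            dets[img] = []
            for _ in range(int(rng.integers(1, 8))):
                c = int(rng.integers(0, 3))
                cx, cy = rng.uniform(0.2, 0.8, 2)
                w, h = rng.uniform(0.05, 0.15, 2)
                gts[img].append((c, cx, cy, w, h))
                if rng.uniform() < 0.8:  # jittered matching detection
                    dets[img].append((c, cx + rng.uniform(-0.01, 0.01),
                                      cy + rng.uniform(-0.01, 0.01),
                                      w * rng.uniform(0.9, 1.1),
                                      h * rng.uniform(0.9, 1.1),
                                      float(rng.uniform(0.3, 1.0))))
            for _ in range(int(rng.integers(0, 3))):  # background FPs
                dets[img].append((int(rng.integers(0, 3)),
                                  *rng.uniform(0.2, 0.8, 2),
                                  *rng.uniform(0.02, 0.08, 2),
                                  float(rng.uniform(0.1, 0.9))))
        summary = evaluate(dets, gts, num_classes=3)
        ref = evaluate_ref(dets, gts, 3, IOU_THRESHOLDS)
        for c, aps in ref.items():
            assert summary.per_class_ap50[c] == pytest.approx(aps[0], abs=1e-6)
            assert summary.per_class_ap50_95[c] == pytest.approx(
                float(np.mean(aps)), abs=1e-6)
        assert summary.map50 == pytest.approx(
            np.mean([a[0] for a in ref.values()]), abs=1e-6)

    def test_strict_thresholds_never_beat_loose(self, rng):
        dets, gts = {}, {}
        for img in range(6):
            gts[img], dets[img] = [], []
            for _ in range(4):
                c = int(rng.integers(0, 2))
                cx, cy = rng.uniform(0.2, 0.8, 2)
                gts[img].append((c, cx, cy, 0.1, 0.1))
                dets[img].append((c, cx + rng.uniform(-0.02, 0.02), cy, 0.1, 0.1,
                                  float(rng.uniform())))
        s = evaluate(dets, gts, num_classes=2)
        assert s.map50_95 <= s.map50 + 1e-12


def test_mean_detection_time():
    assert mean_detection_time([4.0, 6.0]) == 5.0
    assert mean_detection_time([7.3]) == 7.3
    assert mean_detection_time([9.9] * 100) == pytest.approx(9.9)
    with pytest.raises(ValueError):
        mean_detection_time([])
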