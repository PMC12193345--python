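"""Synthetic trap-bottle scenes: determinism, size statistics, augmentation
arithmetic, label round-trips and split arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdayolo.synth import (AUG_OPS, CLASS_NAMES, Annotation, LabelParseError,
                           SceneSpec, augment_image, build_dataset,
                           generate_scene, read_yolo_labels, split_counts,
                           write_yolo_labels)

SMALL = SceneSpec(scale=0.15)


class TestSceneGeneration:
    def test_seeded_determinism(self):
        img1, anns1 = generate_scene(SMALL, seed=11)
        img2, anns2 = generate_scene(SMALL, seed=11)
        assert np.array_equal(img1, img2)
        assert anns1 == anns2

    def test_every_scene_has_one_to_eight_insects(self):
        for seed in range(30):
            _, anns = generate_scene(SMALL, seed=seed)
            assert 1 <= len(anns) <= 8

    def test_annotations_lie_inside_image(self):
        _, anns = generate_scene(SMALL, seed=2)
        for a in anns:
            assert 0 <= a.cx - a.w / 2 and a.cx + a.w / 2 <= 1
            assert 0 <= a.cy - a.h / 2 and a.cy + a.h / 2 <= 1

    def test_species_size_ordering_over_many_scenes(self):
        """Median box diagonal: IMM (8-10 mm) > LGB (2.3-3.0 mm), per the
        body-length priors."""
        diag = {c: [] for c in range(5)}
        spec = SceneSpec(scale=0.25)
        for seed in range(200):
            _, anns = generate_scene(spec, seed=1000 + seed)
            for a in anns:
                diag[a.class_id].append(np.hypot(a.w * spec.w, a.h * spec.h))
        med = {CLASS_NAMES[c]: np.median(v) for c, v in diag.items() if v}
        assert med["IMM"] > med["LGB"]
        assert med["IMM"] == max(med.values())
        assert med["LGB"] == min(med.values())

    def test_boxes_match_rendered_masks(self):
        img, anns, masks = generate_scene(SMALL, seed=4, return_masks=True)
        h, w = img.shape[:2]
        for a, m in zip(anns, masks):
            ys, xs = np.nonzero(m)
            assert a.w * w == pytest.approx(xs.max() - xs.min() + 1)
            assert a.h * h == pytest.approx(ys.max() - ys.min() + 1)


class TestAugmentation:
    def test_hflip_involution(self):
        img, anns = generate_scene(SMALL, seed=6)
        once = augment_image(img, anns, "hflip")
        twice = augment_image(*once, "hflip")
        assert np.array_equal(twice[0], img)
        for a, b in zip(twice[1], anns):
            assert a.cx == pytest.approx(b.cx) and a.cy == pytest.approx(b.cy)

    def test_flip_label_arithmetic(self):
        anns = [Annotation(0, 0.2, 0.7, 0.1, 0.1)]
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        _, h = augment_image(img, anns, "hflip")
        assert (h[0].cx, h[0].cy) == (pytest.approx(0.8), pytest.approx(0.7))
        _, v = augment_image(img, anns, "vflip")
        assert (v[0].cx, v[0].cy) == (pytest.approx(0.2), pytest.approx(0.3))

    def test_photometric_ops_keep_labels_and_bounds(self):
        img, anns = generate_scene(SMALL, seed=7)
        dark, anns_d = augment_image(img, anns, "brightness_down")
        assert np.all(dark <= img)
        assert anns_d == anns
        noisy, anns_n = augment_image(img, anns, "gauss_noise", seed=1)
        assert anns_n == anns
        assert noisy.dtype == np.uint8 and noisy.shape == img.shape
        assert not np.array_equal(noisy, img)

    def test_geometric_flip_commutes_with_mask_boxes(self):
        """Flipping the image and recomputing boxes from the flipped masks
        equals transforming the boxes directly."""
        img, anns, masks = generate_scene(SMALL, seed=8, return_masks=True)
        h, w = img.shape[:2]
        _, flipped = augment_image(img, anns, "hflip")
        for a, fa, m in zip(anns, flipped, masks):
            xs = np.nonzero(m[:, ::-1])[1]
            cx = (xs.min() + xs.max() + 1) / 2 / w
            assert fa.cx == pytest.approx(cx, abs=1e-9)

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError):
            augment_image(np.zeros((4, 4, 3), np.uint8), [], "rotate")


class TestLabelIO:
    def test_format_contract(self, tmp_path):
        p = tmp_path / "a.txt"
        write_yolo_labels([Annotation(1, 0.5, 0.5, 0.1, 0.2)], p)
        assert p.read_text() == "1 0.500000 0.500000 0.100000 0.200000\n"

    def test_empty_roundtrip(self, tmp_path):
        p = tmp_path / "empty.txt"
        write_yolo_labels([], p)
        assert p.read_text() == ""
        assert read_yolo_labels(p) == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 4),
                              st.floats(0.3, 0.7), st.floats(0.3, 0.7),
                              st.floats(0.01, 0.2), st.floats(0.01, 0.2)),
                    max_size=8))
    def test_roundtrip_precision(self, rows):
        import tempfile
        from pathlib import Path
        anns = [Annotation(*r) for r in rows]
        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "r.txt"
            write_yolo_labels(anns, p)
            back = read_yolo_labels(p)
        assert len(back) == len(anns)
        for a, b in zip(anns, back):
            assert a.class_id == b.class_id
            for f in ("cx", "cy", "w", "h"):
                assert abs(getattr(a, f) - getattr(b, f)) <= 5e-7

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.1 0.1\n1 0.2 0.2\n")
        with pytest.raises(LabelParseError, match=":2"):
            read_yolo_labels(p)


class TestDatasetBuild:
    def test_split_arithmetic(self):
        assert split_counts(2000) == (1400, 200, 400)
        assert split_counts(20) == (14, 2, 4)
        with pytest.raises(ValueError):
            split_counts(15)

    def test_small_build_counts_and_disjointness(self, tmp_path):
        man = build_dataset(20, SMALL, tmp_path, seed=3)
        assert (man.n_train, man.n_val, man.n_test) == (56, 2, 4)
        stems = {}
        for split in ("train", "val", "test"):
            files = list((tmp_path / "images" / split).glob("*.png"))
            stems[split] = {f.stem.split("_")[1] for f in files}
            for f in files:
                lbl = tmp_path / "labels" / split / (f.stem + ".txt")
                assert lbl.exists()
        assert not stems["train"] & stems["val"]
        assert not stems["train"] & stems["test"]
        assert not stems["val"] & stems["test"]
        assert len(stems["train"] | stems["val"] | stems["test"]) == 20
        names = {f.stem for f in (tmp_path / "images" / "train").glob("*.png")}
        for op in AUG_OPS:
            assert sum(s.endswith(op) for s in names) == 14

    def test_manifest_yaml_contents(self, tmp_path):
        man = build_dataset(10, SMALL, tmp_path, seed=0)
        import yaml
        data = yaml.safe_load(man.yaml_path.read_text())
        assert data["names"] == ["LGB", "RFB", "IMM", "MW", "AGM"]
        assert data["train"] == "images/train"
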