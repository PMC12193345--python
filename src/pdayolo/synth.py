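"""Synthetic trap-bottle scene generator and dataset builder.

The generator emulates the imaging scenario of a grain-storage monitoring
trap: a transparent cylindrical collection bottle (floor radius 4 cm)
photographed from above at 1100 x 1080 px, its floor scattered with wheat
kernels and debris, holding 1-8 adult insects of five species whose body
lengths follow the published per-species ranges:

    LGB 2.3-3.0 mm, RFB 2.3-4.4 mm, IMM 8.0-10.0 mm,
    MW 2.5-4.5 mm, AGM 4.0-6.0 mm.

Insects are rendered as dark oriented elliptical bodies with a head disc
(moth species additionally get lighter elongated wing shading); each
annotation is the minimum enclosing axis-aligned box of the rendered
mask, in normalized YOLO coordinates.  This is a purely synthetic
stand-in with the right geometry and statistics, not a photorealistic
model.

Datasets are materialized with the standard split arithmetic: a seeded
7:1:2 train/val/test partition, after which every training image is
replaced by its four augmented variants (horizontal flip, vertical flip,
brightness reduction, Gaussian noise), so 2000 scenes become
5600/200/400.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

CLASS_NAMES = ["LGB", "RFB", "IMM", "MW", "AGM"]

#: per-class adult body-length ranges in millimetres
SPECIES_LENGTH_MM = {
    "LGB": (2.3, 3.0),
    "RFB": (2.3, 4.4),
    "IMM": (8.0, 10.0),
    "MW": (2.5, 4.5),
    "AGM": (4.0, 6.0),
}

#: species rendered with moth-like wing shading
MOTH_CLASSES = {"IMM", "AGM"}

AUG_OPS = ("hflip", "vflip", "brightness_down", "gauss_noise")


class PlacementError(RuntimeError):
    pass


class LabelParseError(ValueError):
    pass


@dataclass
class SceneSpec:
    image_w: int = 1100
    image_h: int = 1080
    bottle_radius_mm: float = 40.0      # 4 cm floor radius
    px_per_mm: float = 6.0
    species_table: dict = field(default_factory=lambda: dict(SPECIES_LENGTH_MM))
    min_insects: int = 1
    max_insects: int = 8
    kernel_count: tuple = (25, 60)
    debris_count: tuple = (40, 100)
    scale: float = 1.0                  # render-resolution multiplier
    brightness_factor: float = 0.6
    noise_sigma: float = 10.0

    def __post_init__(self):
        if not 1 <= self.min_insects <= self.max_insects <= 8:
            raise ValueError("insects per image must lie in [1, 8]")
        for name, (lo, hi) in self.species_table.items():
            if not 0 < lo <= hi:
                raise ValueError(f"bad body-length range for {name}")

    @property
    def w(self) -> int:
        return max(8, int(round(self.image_w * self.scale)))

    @property
    def h(self) -> int:
        return max(8, int(round(self.image_h * self.scale)))

    @property
    def radius_px(self) -> float:
        return self.bottle_radius_mm * self.px_per_mm * self.scale


@dataclass
class Annotation:
    """Normalized YOLO box: class id and center/size in [0, 1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not 0 <= self.class_id <= 4:
            raise ValueError(f"class_id {self.class_id} outside 0..4")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box must have positive size")
        for v in (self.cx - self.w / 2, self.cy - self.h / 2,
                  self.cx + self.w / 2, self.cy + self.h / 2):
            if v < -1e-6 or v > 1 + 1e-6:
                raise ValueError("box extends outside the image")


@dataclass
class DatasetManifest:
    out_dir: Path
    yaml_path: Path
    n_train: int
    n_val: int
    n_test: int
    names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))

    @property
    def total(self) -> int:
        return self.n_train + self.n_val + self.n_test


# ------------------------------------------------------------------ drawing
def _ellipse_mask(h, w, cx, cy, a, b, theta, yy, xx):
    """Boolean mask of a rotated ellipse (semi-axes a, b, angle theta)."""
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _render_insect(img, spec: SceneSpec, cls_id: int, rng: np.random.Generator,
                   yy, xx, occupancy):
    """Draw one insect fully inside the bottle disc; returns its mask."""
    name = CLASS_NAMES[cls_id]
    lo, hi = spec.species_table[name]
    length = rng.uniform(lo, hi) * spec.px_per_mm * spec.scale
    length = max(length, 2.0)
    half = length / 2
    width = length * (0.30 if name in MOTH_CLASSES else 0.38)
    theta = rng.uniform(0, np.pi)
    ccx, ccy = spec.w / 2, spec.h / 2
    for _ in range(100):
        rr = spec.radius_px * np.sqrt(rng.uniform()) * 0.92
        ang = rng.uniform(0, 2 * np.pi)
        px, py = ccx + rr * np.cos(ang), ccy + rr * np.sin(ang)
        if np.hypot(px - ccx, py - ccy) + half > spec.radius_px:
            continue
        body = _ellipse_mask(spec.h, spec.w, px, py, half, width / 2, theta, yy, xx)
        hx = px + (half * 0.9) * np.cos(theta)
        hy = py + (half * 0.9) * np.sin(theta)
        head = _ellipse_mask(spec.h, spec.w, hx, hy, length * 0.16, length * 0.14,
                             theta, yy, xx)
        mask = body | head
        if not mask.any() or (occupancy & mask).any():
            continue
        base = np.array([82, 52, 30], float) + rng.uniform(-12, 12, 3)
        img[body] = base
        img[head] = base * 0.75
        if name in MOTH_CLASSES:
            wing = _ellipse_mask(spec.h, spec.w, px - half * 0.25 * np.cos(theta),
                                 py - half * 0.25 * np.sin(theta),
                                 half * 0.7, width * 0.45, theta, yy, xx)
            img[wing & body] = base + np.array([60, 55, 45])
        occupancy |= mask
        return mask
    raise PlacementError(
        f"could not place a {name} insect inside the bottle after 100 tries")


def _mask_to_annotation(mask: np.ndarray, cls_id: int, w: int, h: int) -> Annotation:
    ys, xs = np.nonzero(mask)
    x1, x2 = xs.min(), xs.max() + 1
    y1, y2 = ys.min(), ys.max() + 1
    return Annotation(cls_id, (x1 + x2) / 2 / w, (y1 + y2) / 2 / h,
                      (x2 - x1) / w, (y2 - y1) / h)


def generate_scene(spec: SceneSpec, seed: int, return_masks: bool = False):
    """Render one scene deterministically from (spec, seed).

    Returns (image uint8 HxWx3, [Annotation]); with ``return_masks`` also the
    per-insect boolean masks.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.h, spec.w
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = [58, 57, 60]
    ccx, ccy = w / 2, h / 2
    rad = spec.radius_px
    dist = np.hypot(xx - ccx, yy - ccy)
    disc = dist <= rad
    shade = 1.0 - 0.25 * (dist / max(rad, 1)) ** 2
    for c, v in enumerate((208, 196, 172)):   # translucent bottle floor
        img[..., c][disc] = v * shade[disc]

    # wheat kernels: tan ellipses ~6 x 3 mm
    for _ in range(rng.integers(*spec.kernel_count, endpoint=True)):
        rr = rad * np.sqrt(rng.uniform()) * 0.95
        ang = rng.uniform(0, 2 * np.pi)
        kx, ky = ccx + rr * np.cos(ang), ccy + rr * np.sin(ang)
        ka = rng.uniform(2.4, 3.4) * spec.px_per_mm * spec.scale / 2
        kb = ka * rng.uniform(0.45, 0.6)
        km = _ellipse_mask(h, w, kx, ky, max(ka, 1), max(kb, 0.8),
                           rng.uniform(0, np.pi), yy, xx) & disc
        img[km] = np.array([196, 160, 96], float) + rng.uniform(-25, 25, 3)

    # debris specks
    for _ in range(rng.integers(*spec.debris_count, endpoint=True)):
        rr = rad * np.sqrt(rng.uniform()) * 0.98
        ang = rng.uniform(0, 2 * np.pi)
        dx, dy = ccx + rr * np.cos(ang), ccy + rr * np.sin(ang)
        dm = _ellipse_mask(h, w, dx, dy, rng.uniform(0.8, 2.2), rng.uniform(0.6, 1.6),
                           rng.uniform(0, np.pi), yy, xx) & disc
        img[dm] = np.array([150, 126, 84], float) + rng.uniform(-30, 30, 3)

    occupancy = np.zeros((h, w), dtype=bool)
    k = int(rng.integers(spec.min_insects, spec.max_insects, endpoint=True))
    annotations, masks = [], []
    for _ in range(k):
        cls_id = int(rng.integers(0, 5))
        mask = _render_insect(img, spec, cls_id, rng, yy, xx, occupancy)
        annotations.append(_mask_to_annotation(mask, cls_id, w, h))
        masks.append(mask)
    out = np.clip(img, 0, 255).astype(np.uint8)
    if return_masks:
        return out, annotations, masks
    return out, annotations


# ------------------------------------------------------------- augmentation
def augment_image(image: np.ndarray, annotations: list[Annotation], op_name: str,
                  spec: SceneSpec | None = None, seed: int = 0):
    """Apply one augmentation; geometric ops transform the boxes, photometric
    ops leave them unchanged."""
    spec = spec or SceneSpec()
    if op_name == "hflip":
        out = image[:, ::-1].copy()
        anns = [Annotation(a.class_id, 1.0 - a.cx, a.cy, a.w, a.h)
                for a in annotations]
    elif op_name == "vflip":
        out = image[::-1].copy()
        anns = [Annotation(a.class_id, a.cx, 1.0 - a.cy, a.w, a.h)
                for a in annotations]
    elif op_name == "brightness_down":
        out = np.clip(image.astype(np.float64) * spec.brightness_factor,
                      0, 255).astype(np.uint8)
        anns = list(annotations)
    elif op_name == "gauss_noise":
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, spec.noise_sigma, image.shape)
        out = np.clip(image.astype(np.float64) + noise, 0, 255).astype(np.uint8)
        anns = list(annotations)
    else:
        raise ValueError(f"unknown augmentation {op_name!r}; "
                         f"expected one of {AUG_OPS}")
    return out, anns


# ----------------------------------------------------------------- label IO
def write_yolo_labels(annotations: list[Annotation], path):
    path = Path(path)
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}"
             for a in annotations]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path) -> list[Annotation]:
    path = Path(path)
    out = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cid = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as err:
            raise LabelParseError(f"{path}:{ln}: {err}") from err
        out.append(Annotation(cid, cx, cy, w, h))
    return out


# ------------------------------------------------------------ dataset build
def split_counts(n_images: int) -> tuple[int, int, int]:
    """7:1:2 split sizes (before augmentation)."""
    if n_images % 10:
        raise ValueError("n_images must be divisible by 10 for a 7:1:2 split")
    return 7 * n_images // 10, n_images // 10, 2 * n_images // 10


def build_dataset(n_images: int, spec: SceneSpec, out_dir, seed: int = 0) -> DatasetManifest:
    """Generate scenes, split 7:1:2, replace each training image by its four
    augmented variants, write images + YOLO labels + a dataset YAML."""
    n_train, n_val, n_test = split_counts(n_images)
    out_dir = Path(out_dir)
    try:
        for sub in ("images", "labels"):
            for split in ("train", "val", "test"):
                (out_dir / sub / split).mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise IOError(f"cannot create dataset directories under {out_dir}: {err}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_images)
    splits = {"train": order[:n_train], "val": order[n_train:n_train + n_val],
              "test": order[n_train + n_val:]}
    counts = {}
    for split, idxs in splits.items():
        written = 0
        for i in idxs:
            image, anns = generate_scene(spec, seed=seed * 1_000_003 + int(i))
            stem = f"scene_{i:05d}"
            if split == "train":
                # originals are not retained: each train image becomes its
                # four augmented variants
                for op in AUG_OPS:
                    aug, aug_anns = augment_image(image, anns, op, spec,
                                                  seed=seed * 7 + int(i))
                    name = f"{stem}_{op}"
                    Image.fromarray(aug).save(out_dir / "images" / split / f"{name}.png")
                    write_yolo_labels(aug_anns, out_dir / "labels" / split / f"{name}.txt")
                    written += 1
            else:
                Image.fromarray(image).save(out_dir / "images" / split / f"{stem}.png")
                write_yolo_labels(anns, out_dir / "labels" / split / f"{stem}.txt")
                written += 1
        counts[split] = written

    yaml_path = out_dir / "dataset.yaml"
    yaml_path.write_text(yaml.safe_dump({
        "path": ".", "train": "images/train", "val": "images/val",
        "test": "images/test", "names": list(CLASS_NAMES)}, sort_keys=False))
    return DatasetManifest(out_dir, yaml_path, counts["train"], counts["val"],
                           counts["test"])
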