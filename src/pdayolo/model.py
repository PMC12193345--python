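"""Detector assembly: the baseline network, the modified variants, and the
analytic FLOPs accountant.

The baseline is a nano-scale one-stage detector (YOLO11n layout: depth
multiple 0.5, width multiple 0.25, max 1024 channels) with three detection
scales at strides 8/16/32.  The three modifications are orthogonal
substitutions, so all eight ablation variants are constructible:

* ``use_pf_c3k2``  — every C3k2 block becomes PF_C3k2;
* ``use_aifi``     — the SPPF stage is replaced by an AIFI block;
* ``use_dmae``     — a channel-preserving DMAE is inserted at each of the
  three neck outputs (P3/P4/P5) feeding the detection head.

``count_flops`` reports the analytic cost of one forward pass: 2 FLOPs per
multiply-accumulate, counted for parameterized convolution and linear
layers with conv + batch-norm fused; parameter-free ops and data-dependent
attention matmuls are excluded.  The count depends only on the
architecture and input size, never on parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import blocks as B
from .aifi import AIFI
from .dmae import DMAE, DMAEConfig
from .nn import autograd as ag
from .nn import (Conv2d, ConvBNAct, DWConv, FlopCounter, Module, Sequential,
                 Tensor, init_scope)

REG_MAX = 16
STRIDES = (8, 16, 32)
CLASS_NAMES = ["LGB", "RFB", "IMM", "MW", "AGM"]


@dataclass(frozen=True)
class ModelVariant:
    use_pf_c3k2: bool = False
    use_dmae: bool = False
    use_aifi: bool = False

    @classmethod
    def from_string(cls, s: str) -> "ModelVariant":
        """Parse e.g. 'pf,dmae,aifi' (empty string -> baseline)."""
        toks = {t.strip().lower() for t in s.split(",") if t.strip()}
        known = {"pf", "dmae", "aifi"}
        if toks - known:
            raise ValueError(f"unknown variant tokens {toks - known}")
        return cls("pf" in toks, "dmae" in toks, "aifi" in toks)

    def label(self) -> str:
        toks = [t for t, on in (("pf", self.use_pf_c3k2), ("dmae", self.use_dmae),
                                ("aifi", self.use_aifi)) if on]
        return "+".join(toks) if toks else "baseline"


ALL_VARIANTS = [ModelVariant(pf, dm, ai)
                for pf in (False, True) for dm in (False, True) for ai in (False, True)]


@dataclass
class ModelStats:
    gflops: float
    params: int
    input_size: int


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the detector's standard recipe."""

    epochs: int = 150
    batch: int = 16
    lr: float = 0.01
    optimizer: str = "SGD"
    image_size: int = 640
    momentum: float = 0.937
    weight_decay: float = 0.0005
    seed: int = 0

    def as_dict(self) -> dict:
        return {"epochs": self.epochs, "batch": self.batch, "lr": self.lr,
                "optimizer": self.optimizer,
                "image_size": f"{self.image_size} x {self.image_size}",
                "momentum": self.momentum, "weight_decay": self.weight_decay,
                "seed": self.seed}


# ------------------------------------------------------------- architecture
def model_spec(variant: ModelVariant, num_classes: int = 5) -> list[dict]:
    """The network as a plain layer list (name, inputs, block, args); this
    structure round-trips through YAML and is what the builder consumes."""
    c3k2 = "PFC3k2" if variant.use_pf_c3k2 else "C3k2"
    spec = [
        dict(name="b0", inputs=["image"], block="Conv", args=dict(c1=3, c2=16, k=3, s=2)),
        dict(name="b1", inputs=["b0"], block="Conv", args=dict(c1=16, c2=32, k=3, s=2)),
        dict(name="b2", inputs=["b1"], block=c3k2, args=dict(c1=32, c2=64, n=1, c3k=False, e=0.25)),
        dict(name="b3", inputs=["b2"], block="Conv", args=dict(c1=64, c2=64, k=3, s=2)),
        dict(name="b4", inputs=["b3"], block=c3k2, args=dict(c1=64, c2=128, n=1, c3k=False, e=0.25)),
        dict(name="b5", inputs=["b4"], block="Conv", args=dict(c1=128, c2=128, k=3, s=2)),
        dict(name="b6", inputs=["b5"], block=c3k2, args=dict(c1=128, c2=128, n=1, c3k=True)),
        dict(name="b7", inputs=["b6"], block="Conv", args=dict(c1=128, c2=256, k=3, s=2)),
        dict(name="b8", inputs=["b7"], block=c3k2, args=dict(c1=256, c2=256, n=1, c3k=True)),
    ]
    if variant.use_aifi:
        spec.append(dict(name="b9", inputs=["b8"], block="AIFI",
                         args=dict(c=256, heads=8, hidden=512)))
    else:
        spec.append(dict(name="b9", inputs=["b8"], block="SPPF",
                         args=dict(c1=256, c2=256, k=5)))
    spec += [
        dict(name="b10", inputs=["b9"], block="C2PSA", args=dict(c1=256, c2=256, n=1)),
        dict(name="u11", inputs=["b10"], block="Upsample", args={}),
        dict(name="c12", inputs=["u11", "b6"], block="Concat", args={}),
        dict(name="h13", inputs=["c12"], block=c3k2, args=dict(c1=384, c2=128, n=1, c3k=False)),
        dict(name="u14", inputs=["h13"], block="Upsample", args={}),
        dict(name="c15", inputs=["u14", "b4"], block="Concat", args={}),
        dict(name="h16", inputs=["c15"], block=c3k2, args=dict(c1=256, c2=64, n=1, c3k=False)),
        dict(name="h17", inputs=["h16"], block="Conv", args=dict(c1=64, c2=64, k=3, s=2)),
        dict(name="c18", inputs=["h17", "h13"], block="Concat", args={}),
        dict(name="h19", inputs=["c18"], block=c3k2, args=dict(c1=192, c2=128, n=1, c3k=False)),
        dict(name="h20", inputs=["h19"], block="Conv", args=dict(c1=128, c2=128, k=3, s=2)),
        dict(name="c21", inputs=["h20", "b10"], block="Concat", args={}),
        dict(name="h22", inputs=["c21"], block=c3k2, args=dict(c1=384, c2=256, n=1, c3k=True)),
    ]
    p3, p4, p5 = "h16", "h19", "h22"
    if variant.use_dmae:
        for nm, src, c in (("dmae_p3", p3, 64), ("dmae_p4", p4, 128), ("dmae_p5", p5, 256)):
            spec.append(dict(name=nm, inputs=[src], block="DMAE", args=dict(c=c)))
        p3, p4, p5 = "dmae_p3", "dmae_p4", "dmae_p5"
    spec.append(dict(name="detect", inputs=[p3, p4, p5], block="Detect",
                     args=dict(nc=num_classes, ch=[64, 128, 256])))
    return spec


def spec_to_yaml(spec: list[dict]) -> str:
    return yaml.safe_dump(spec, sort_keys=False)


def spec_from_yaml(text: str) -> list[dict]:
    return yaml.safe_load(text)


class Detect(Module):
    """Decoupled anchor-free detection head at three scales.

    Per scale: a box branch regressing 4 distance distributions over
    ``REG_MAX`` bins (decoded by their softmax expectation) and a
    depthwise-separable classification branch with per-class logits.
    """

    def __init__(self, nc: int, ch):
        super().__init__()
        if nc < 1:
            raise ValueError("num_classes must be >= 1")
        self.nc = nc
        c2 = max(16, ch[0] // 4, 4 * REG_MAX)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = [Sequential(ConvBNAct(x, c2, 3), ConvBNAct(c2, c2, 3),
                               Conv2d(c2, 4 * REG_MAX, 1)) for x in ch]
        self.cv3 = [Sequential(DWConv(x, x, 3), ConvBNAct(x, c3, 1),
                               DWConv(c3, c3, 3), ConvBNAct(c3, c3, 1),
                               Conv2d(c3, nc, 1)) for x in ch]
        # fixed (non-trainable) bin-expectation projection, counted as a conv
        self.dfl_w = np.arange(REG_MAX, dtype=np.float32)

    def forward(self, feats):
        out = []
        for f, cv2, cv3 in zip(feats, self.cv2, self.cv3):
            box = cv2(f)
            if FlopCounter._active:   # the DFL projection conv
                n, _, h, w = box.shape
                FlopCounter._active[-1].flops += 2 * n * 4 * h * w * REG_MAX
            out.append((box, cv3(f)))
        return out


_BLOCKS = {
    "Conv": lambda args: ConvBNAct(**args),
    "C3k2": lambda args: B.C3k2(**args),
    "PFC3k2": lambda args: B.PFC3k2(**args),
    "SPPF": lambda args: B.SPPF(**args),
    "AIFI": lambda args: AIFI(**args),
    "C2PSA": lambda args: B.C2PSA(**args),
    "DMAE": lambda args: DMAE(DMAEConfig(in_channels=args["c"])),
}


class DetectionModel(Module):
    def __init__(self, spec: list[dict], num_classes: int = 5):
        super().__init__()
        self.spec = spec
        self.num_classes = num_classes
        self.layers = []
        self.layer_names = []
        for entry in spec:
            name, block, args = entry["name"], entry["block"], entry["args"]
            try:
                if block in ("Upsample", "Concat"):
                    mod = None
                elif block == "Detect":
                    mod = Detect(args["nc"], args["ch"])
                else:
                    mod = _BLOCKS[block](args)
            except (KeyError, ValueError, TypeError) as err:
                raise ValueError(f"invalid configuration at layer {name!r} "
                                 f"({block}): {err}") from err
            if mod is not None:
                self.layers.append(mod)
                self.layer_names.append(name)
        self._by_name = dict(zip(self.layer_names, self.layers))

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        cache = {"image": x}
        out = None
        for entry in self.spec:
            name, block = entry["name"], entry["block"]
            ins = [cache[i] for i in entry["inputs"]]
            if block == "Upsample":
                y = ag.upsample_nearest2x(ins[0])
            elif block == "Concat":
                y = ag.concat(ins, axis=1)
            elif block == "Detect":
                y = self._by_name[name](ins)
            else:
                y = self._by_name[name](ins[0])
            cache[name] = y
            out = y
        return out  # list of (box_logits, cls_logits) at strides 8/16/32

    def census(self) -> dict:
        """Exact-type layer counts, e.g. {'C3k2': 8, 'SPPF': 1, ...}."""
        counts: dict[str, int] = {}
        for m in self.modules():
            counts[type(m).__name__] = counts.get(type(m).__name__, 0) + 1
        return counts


def build_model(v: ModelVariant, num_classes: int = 5, seed: int = 0) -> DetectionModel:
    if num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    with init_scope(seed):
        model = DetectionModel(model_spec(v, num_classes), num_classes)
    model.variant = v
    return model


def count_flops(model: DetectionModel, input_size: int = 640) -> ModelStats:
    was_training = model.training
    model.eval()
    x = np.zeros((1, 3, input_size, input_size), dtype=np.float32)
    with FlopCounter() as fc:
        model(x)
    model.train(was_training)
    return ModelStats(gflops=fc.flops / 1e9, params=model.num_params(),
                      input_size=input_size)


def count_module_flops(module: Module, c: int, h: int, w: int) -> int:
    """Analytic FLOPs of a single block on a (1, c, h, w) input."""
    was_training = module.training
    module.eval()
    with FlopCounter() as fc:
        module(Tensor(np.zeros((1, c, h, w), dtype=np.float32)))
    module.train(was_training)
    return fc.flops
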