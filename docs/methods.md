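# Methods

## Scope and shape of the implementation

The package implements a nano-scale one-stage detector with three
architectural modifications (PoolFormer-based PF_C3k2 blocks, the DMAE
edge module, the AIFI attention stage), an analytic FLOPs accountant, the
standard detection metrics, and a synthetic trap-bottle scene generator.
Everything — convolution, pooling, resampling, normalization, attention,
and their gradients — is implemented on NumPy in `pdayolo/nn`, a small
reverse-mode autodiff engine, so the package has no deep-learning framework
dependency. Training accuracy of the real system is *not* the claim here:
the proprietary trap imagery does not exist in this repository and GPU-scale
training is out of scope. What the tests establish is that every block
computes exactly what its definition says (loop-based oracles at ≤ 8×8×8,
tolerance 1e-5), that the cost ledger of the architecture is reproduced,
and that the full pipeline (synthesize → train → predict → evaluate) runs
end to end and optimizes.

## Network

Baseline: YOLO11n layout (depth multiple 0.5 → single inner repeats, width
multiple 0.25, max 1024 channels), backbone C3k2 stages with the boolean
C3k/Bottleneck switch per the published layer table, SPPF + C2PSA at the
deepest level, PAN-style neck, decoupled anchor-free head with 16-bin
distance distributions (DFL) per side and depthwise-separable
classification branches. Input is NCHW, 640×640×3 for cost-comparable
numbers.

Variant substitutions are orthogonal by construction:

* `use_pf_c3k2` rebuilds every C3k2 as PF_C3k2, identical topology, inner
  Bottleneck → PoolFormer block (false path) or C3k → PF_C3k, i.e. C3k with
  its Bottlenecks replaced by PoolFormer blocks (true path). Where the
  block diagram leaves the internal wiring of PF_C3k ambiguous, we pin
  "replace each Bottleneck inside C3k, keep C3k's three convolutions";
  this reading also reproduces the published cost delta exactly.
* `use_aifi` swaps SPPF for AIFI at the stride-32 map.
* `use_dmae` appends one channel-preserving DMAE at each of the three neck
  outputs feeding the head (the sources only say "into the neck"; this
  placement is validated through the cost budget).

## PoolFormer block

`y = x + (AvgPool3×3(LN(x)) − LN(x))`, `out = y + MLP(LN(y))` with the MLP
two pointwise convolutions (expansion 4, GELU between). Design choices:

* Average pooling is stride 1, padding 1, with a divisor that counts only
  in-image cells. This makes "constant input ⇒ zero mixer output" exact at
  the borders, which is both the natural reading of a local mean and
  directly testable.
* The "− x" subtraction follows the canonical PoolFormer token mixer; with
  the residual connection the two cancel for constant inputs.
* LayerNorm acts along the channel axis independently at each spatial
  position.
* GELU uses the tanh approximation (bit-compatible with common framework
  defaults to ~1e-7, and free of special functions).

## DMAE

`feat_rls = [3, 6, 9, 12]` adaptive-pooling target resolutions, reduction
ratio 2 for the branch 1×1 convolutions. Each edge branch is
pool → 1×1 conv (c → c/2) → 3×3 DSConv → EFE → bilinear upsample to the
input size. The local branch is a 3×3 DSConv that also emits c/2 channels,
so all n+1 branches enter the weighted concat at equal width; the 1×1
fusion conv restores the input channel count (channel-preserving, so the
module drops into the neck without rewiring). The CWG is global average
pool → 1×1 conv (c → c/8) → ReLU → 1×1 conv (→ n+1) → sigmoid: one
independent scalar gate per branch (independent sigmoids rather than a
softmax across branches, because the weights are applied branch-by-branch;
a softmax would couple them).

Numerical/degenerate-input choices:

* `edge_branch_forward` rejects a target resolution larger than the input
  map (adaptive *average* pooling cannot upsample). The assembled DMAE
  module instead clamps each branch resolution to `min(r, H, W)` at run
  time, so the full detector still trains at small image sizes (at
  160×160 the stride-32 map is 5×5, below the largest configured
  resolution).
* Upsampling back to the input resolution is bilinear with half-pixel
  alignment; the adaptive pool uses floor/ceil window partitioning, so
  exact-divisor cases (6→3) are disjoint block means, tested bit-exactly.
* DSConv here means depthwise k×k then pointwise 1×1 with plain biases and
  no normalization — the EFE applies its own sigmoid, and the identities
  "zero weights ⇒ output ≡ F_in + 0.5" and "centered delta + identity
  pointwise ⇒ identity" hold exactly.

## AIFI

Tokens are the flattened deepest feature map; 2-D sinusoidal positional
encodings (temperature 10000, quarter-split sin/cos of x and y
frequencies; every token has squared norm d/2) are added to the query and
key inputs only, values are unmodified. Post-norm placement: residual then
LayerNorm, twice. Heads = 8. The MLP hidden width is 512 for 256-dim
tokens: the sources do not state it, and 512 is the value at which the
stage's analytic cost matches the published +0.3 G budget under our
counting convention (with hidden 1024 the stage would cost +0.5 G when its
projection layers are counted). No dropout anywhere; the block is a
deterministic function of its parameters.

## FLOPs accounting

Convention: **2 FLOPs per multiply-accumulate, counted for parameterized
convolution and linear layers only** (including attention Q/K/V/output
projections, depthwise convolutions and the DFL projection);
conv + batch-norm pairs count as fused; parameter-free operations
(pooling, resampling, activations, softmax, concatenation) and the
data-dependent attention matmuls QKᵀ and AV are excluded. This is the
convention under which the baseline's published 6.3 G figure is
reproduced (we measure 6.315 G at 640×640 with 5 classes), and it matches
common profiler practice. Counts are accumulated during a real forward
pass, so they depend only on architecture and input size, never on
parameter values. Measured ledger at 640×640 (GFLOPs): baseline 6.315,
PF only 6.053, AIFI only 6.603, DMAE only 6.848, full 6.875 — module
deltas −0.262 / +0.288 / +0.533, additive to machine precision because
the three substitutions are structurally independent.

## Training and inference plumbing

The loss is intentionally plain (none of the architectural contributions
touch the loss): each ground-truth box is assigned to the cell containing
its center at one scale chosen by box size (boxes whose long side fits the
stride-8 regression range go to P3, etc.); positives get a one-hot class
target and target distances (left/top/right/bottom from the cell center in
stride units, clamped to the 16-bin range); the objective is mean BCE over
all class logits plus an L1 penalty between DFL-expected and target
distances at positive cells. Optimizer: SGD with momentum 0.937 and weight
decay 5e-4, defaults epochs 150 / batch 16 / lr 0.01 / image size 640.
Parameter initialization is Kaiming-normal from a single seeded generator,
so identical (variant, seed) pairs produce identical parameter checksums.

Inference decodes the expected bin distances around cell centers, applies
sigmoid class confidences, clips boxes to the image, and runs class-wise
greedy NMS (IoU 0.45 default; confidence 0.001 for evaluation sweeps).

## Evaluation

Greedy class-wise matching (highest-IoU unmatched ground truth, one use
per ground truth), P/R/F1 from the IoU-0.5 counts with the degenerate
conventions P = 0 when TP+FP = 0 and F1 = 0 when P+R = 0. AP integrates
the precision envelope on a 101-point recall grid by default (matching the
mAP@0.5:0.95 convention); the exact all-point envelope integral is
available via `interpolation="envelope"` since the original choice is
unstated. Classes with no ground truth are skipped and recorded. Mean
detection time covers forward + decode + NMS only and is reported, never
asserted (hardware-dependent).

## Synthetic data

The generator emulates the trap-bottle acquisition setup: 1100×1080 px
frames, a cylindrical bottle floor of physical radius 4 cm rendered as a
shaded disc, wheat kernels (~2.4–3.4 mm tan ellipses) and debris specks,
and 1–8 insects per scene drawn uniformly over the five classes with body
length sampled uniformly from the per-species ranges (LGB 2.3–3.0 mm,
RFB 2.3–4.4 mm, IMM 8.0–10.0 mm, MW 2.5–4.5 mm, AGM 4.0–6.0 mm). The
imaging scale is 6 px/mm (240 px bottle radius leaves margin in the
frame); a `scale` factor renders geometrically identical scenes at reduced
resolution — split and count arithmetic are resolution-independent.
Insects are dark oriented ellipses with a head disc; the moth classes get
lighter wing shading for inter-class appearance contrast. Boxes are the
minimum enclosing axis-aligned rectangles of the rendered masks.
Placement retries up to 100 positions fully inside the disc without
overlapping previously placed insects, then raises a placement error.

Augmentation: horizontal flip (cx → 1−cx), vertical flip (cy → 1−cy),
brightness reduction (×0.6, clamped) and zero-mean Gaussian noise
(σ = 10 on the 8-bit scale, seeded); the photometric ops leave boxes
unchanged. Dataset builds split scenes 7:1:2 by a seeded shuffle, then
replace each training image by its four augmented variants (originals are
not retained in the training split — this is the reading under which
1400 × 4 = 5600), giving 5600/200/400 from 2000 scenes.

What the generator does *not* model: photorealistic insect appearance,
occlusion inside grain masses, perspective or lighting variation, motion
blur. Tests passing on this data show that the geometry, label plumbing,
optimization and evaluation are correct — not that field accuracy would
match any published figure.

## Problem sizes used in the checked-in tests

FLOPs are counted at the full 640×640 input. The dataset-arithmetic check
renders all 2000 scenes at 0.08× resolution (counts are scale-invariant by
construction). The training smoke test uses the full modified detector on
8 synthetic 160×160 images for 30 epochs of full-batch SGD on CPU and
asserts that the loss decreases and that the trained model returns
detections on its training images; no accuracy threshold is asserted at
this scale. Block-level oracle comparisons use inputs of at most 8×8×8 at
tolerance 1e-5; gradient checks use float64 central differences.

## Known limitations

* The NumPy engine is single-threaded except for BLAS matmuls; it is meant
  for correctness and desk-scale experiments, not large-scale training.
* The training loss is a minimal center-cell assigner; a production system
  would use an IoU-aware task-aligned assigner and CIoU/DFL losses.
* `mean_detection_time_ms` values on this engine are not comparable to
  GPU-framework timings.
* Bottle-floor rendering is 2-D; the bottle wall and parallax are ignored.
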