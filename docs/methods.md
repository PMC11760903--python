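# Methods

`algadet` implements the computational core of a feature-enhanced
single-stage microalgae detector as a reusable, tested toolkit: the box
regression losses (IoU, CIoU, SIoU), the CAGS coordinate-attention block,
the detection evaluation suite, a synthetic scene generator, and a tiny
reference detector that ties them together at desk scale.  This note
records the models, the defaults, and the design choices that were
genuinely open.

## Box regression losses

All losses operate on axis-aligned boxes in center format `(cx, cy, w, h)`
with strictly positive extents; degenerate boxes are rejected rather than
clamped so that annotation bugs surface at the boundary.

**CIoU.** `1 − IoU + ρ²/c² + αv`, where ρ is the center distance, c the
diagonal of the smallest enclosing box, `v = (4/π²)(arctan(w_gt/h_gt) −
arctan(w/h))²` the aspect-consistency term and `α = v/((1−IoU)+v)` its
balance weight.  Two numerical conventions: α is defined as 0 when
`(1−IoU)+v = 0` (identical boxes; every continuous extension gives loss 0
there), and α is treated as a constant in the gradient path, following the
original CIoU training convention.

**SIoU.** `1 − IoU + (Δ + Ω)/2` with three geometric costs:

* *Angle cost* `Λ = 1 − 2·sin²(arcsin(d_y/σ) − π/4)`: 0 when the line
  joining the two centers is axis-aligned, 1 at 45°.  The scalar API
  implements this form literally; the vectorized/differentiable core uses
  the algebraically identical `Λ = 2·|d_x|·|d_y|/σ²`, which is smooth
  everywhere (the arcsin form has an infinite derivative at exact vertical
  alignment).  `Λ := 0` for coincident centers — Δ is 0 there regardless,
  so the convention only affects the reported breakdown, never the loss.
* *Distance cost* `Δ = Σ_{t∈{x,y}} (1 − e^{−γρ_t})` with `ρ_x, ρ_y` the
  squared center offsets normalized by the enclosing box and `γ = 2 − Λ`:
  off-axis pairs are penalized less steeply.
* *Shape cost* `Ω = Σ_{t∈{w,h}} (1 − e^{−w_t})^θ` with `w_w, w_h` the
  relative width/height mismatches.  θ (default 4, admissible range
  [2, 6]) controls how much shape mismatch is emphasized; it is a config
  knob recorded in every run manifest.

The substantive difference between the two: CIoU's `v` vanishes exactly
whenever the aspect ratios agree, even for very different sizes, which
destabilizes convergence near that manifold; SIoU's Ω stays positive
whenever sizes differ.  This is asserted as a test (power-of-two size
scalings keep the float aspect ratio exactly equal).

One symbol subtlety: the angle cost's "center height difference" and the
enclosure height are distinct quantities that share a symbol in common
write-ups; `EnclosureGeometry` keeps them apart as `center_dy` and
`enclose_h`.

All loss math runs in double precision.  The batched path is a single
vectorized implementation verified against an independent straight-line
scalar transcription (max |Δ| < 1e-6 on 1000 seeded random pairs).

## Automatic differentiation

No deep-learning framework is part of the package's dependency set; the
learnable components run on a small in-package reverse-mode engine
(`algadet.autodiff`): a `Tensor` wraps an ndarray and records primitive
operations on a tape, with exactly the primitives the package needs
(arithmetic, exp/log/arctan/arcsin/sigmoid, reductions, slicing/scatter,
concatenation, matmul, broadcasting).  Every dispatching helper also
accepts plain ndarrays, so the loss code is written once and runs with or
without gradient tracking.  Gradients are verified against central finite
differences for the primitives, for the full CAGS block (inputs and all
parameters, atol 1e-6) and for the batched SIoU loss.

## CAGS block

Coordinate attention pools the feature map `[C, H, W]` along each spatial
direction (`[C, H, 1]` and `[C, 1, W]`), merges the descriptors into
`[C, H+W, 1]`, and learns per-direction sigmoid gates from the merged
descriptor; the input is reweighted multiplicatively by both gates.  The
shared transform is a GSConv: a dense 1×1 convolution to half the
intermediate width, a depth-wise convolution (kernel 5 along the merged
axis) stacked on its output for the other half, concatenation, and a
reshape–transpose channel shuffle (groups = 2, matching the two branches
it mixes).

Defaults and open choices:

* intermediate width `mid = max(8, C/32)`, rounded up to even so GSConv
  can split it — the coordinate-attention convention; config knob.
* normalization = per-channel standardization over the merged axis with a
  learnable affine; nonlinearity = SiLU.  Both knobs.
* the depth-wise branch consumes the dense branch's output (the serial
  reading of the GSConv dataflow), not the raw input; flagged in config.
* fusion is pure multiplicative gating by default; an additive-residual
  variant is available as `residual=True`.
* **neutral gate initialization** (default on): the two gate projections
  are zero-initialized so both gates start at exactly 0.5 everywhere — a
  position-independent scale that leaves the feature geometry untouched
  until the gates are learned.  Randomly initialized gates act as a fixed
  random position-dependent distortion, which measurably destroys the
  linear separability of downstream features in short training runs.

Contracts asserted in tests: output shape = input shape; `|out| ≤ |in|`
element-wise (sigmoid gates < 1); channel shuffle is an invertible
permutation; bit-identical forward passes under a fixed seed; finite
gradients everywhere.

## Evaluation suite

* **Matching**: greedy, per image and class, in descending confidence;
  a prediction claims its highest-IoU unmatched ground truth if
  IoU ≥ τ; each ground truth is consumed at most once; leftovers are
  false negatives.  (The counts are standard; the assignment protocol is
  the evaluator's and is recorded in run manifests.)
* **P/R**: `TP/(TP+FP)` and `TP/(TP+FN)`, 0 on empty denominators.
* **AP**: area under the precision–recall curve with the monotone
  right-envelope (all-points) interpolation — the continuous form of the
  integral definition; an 11-point variant is available for
  comparability.  Ties in score sort stably by input order, making AP
  reproducible.
* **mAP**: class mean; `map50` at τ = 0.5, `map5095` averaged over
  τ ∈ {0.50, 0.55, …, 0.95}.  Classes with neither ground truth nor
  predictions are dropped from the mean.
* **ROC/AUC**: the pairwise indicator form (1 per positive/negative pair
  where the positive outranks, 0.5 per tie, divided by P·N), equal to the
  trapezoidal area under the threshold-swept ROC and to the Mann–Whitney
  U statistic divided by P·N (cross-checked to 1e-9).  A detector has no
  natural negative class, so per-class score sets use a documented
  one-vs-rest construction: matched detection scores are positives,
  unmatched are negatives; AUC is undefined (NaN) when either set is
  empty.

## Synthetic scenes

The generator renders bright-field-like micrographs: a bright textured
background (smoothed Gaussian noise) with darker cells drawn as
parametric caricatures of seven morphologies (chain of beads, small disc,
lobed rosette, ovoid, flagellated ellipse, teardrop, thin spindle).  The
shapes are controllable stand-ins, not renderings of real taxa: their
role is exact ground truth at controllable difficulty (size, density,
contrast, overlap).  Per-class base intensities are spread over [0.14,
0.62] with per-instance jitter — distinct optical densities per taxon —
which together with morphology carries the class signal.

Geometry conventions: 0-based pixel grid, pixel centers at half-integer
coordinates; a recorded box is the exact tight bounding box of the
rendered mask, stored normalized in YOLO center format (`class cx cy w h`,
six decimals, one text file per image; prediction files append a
confidence column).

Each scene is single-species (the capture regime of cultured samples);
`build_dataset` balances image counts over classes, splits 8:1:1 per
class with largest-remainder rounding, and writes a manifest with every
seed and file hash, so identical seeds give identical bytes.
Augmentation mirrors the standard small-corpus pipeline: salt-and-pepper
impulse noise replacing exactly `round(p·n)` pixels (half minimum, half
maximum intensity; the odd pixel assigned by a seeded draw; default
p = 0.02 when enabled) and random scaling (default range [0.8, 1.2]),
either whole-image (normalized labels unchanged) or scale-then-crop/pad
with box remapping and a visible-area drop threshold (default 25%).
Neither density nor range is a literature value; both are config knobs.

The `easy` preset (2–4 large, well-separated, high-contrast cells on
128 px images) models a clean single-culture capture; it is the fixture
for desk-scale end-to-end runs.

**What passing tests do and do not show.** The generator provides exact
labels and controllable difficulty, so it validates the machinery (losses,
attention, evaluator, trainer plumbing) end to end.  It does not emulate
real micrograph nuisances — focus gradients, debris, clumping, staining
variability, class-imbalanced mixtures — so passing the end-to-end fixture
says nothing quantitative about detection accuracy on real microscopy
data.

## Tiny reference detector

A deliberately minimal single-scale anchor head, not a full-scale
detector replica: grid stride 8, one square anchor (4 strides) per cell,
fixed hand-crafted per-cell features, CAGS optionally inserted on the
feature map, and a learnable pointwise head producing objectness, box
offsets and class logits per cell.  Offsets decode YOLO-style with the
extended ±0.5-cell range (`2σ(t) − 0.5`), so cells adjacent to an object
center can regress onto it; width/height scale the anchor exponentially.

Features per cell (fitted scaler standardizes channels over the training
set): 6×6 block means of a 24 px patch (orientation cues for box
regression); radial ring mean/std profiles plus window statistics over a
48 px window and darkness-weighted moment invariants (mass, spread,
elongation, dark fraction) — rotation-invariant morphology cues, because
cells appear at arbitrary orientation and raw patches generalize poorly
from ~170 training instances; and the oriented second moments
(√cxx, √cyy, correlation) as direct linear cues for the extents of thin
rotated shapes.

Targets: the cell containing an object center carries objectness 1; every
cell whose center falls inside the object's box carries the class and box
targets (it sees mostly object pixels) and is excluded from the
objectness loss rather than forced to call itself background.  The loss
is a weighted sum: objectness binary cross-entropy over all non-ignored
cells (positives up-weighted ×16 against the dense-grid imbalance),
softmax cross-entropy on covered cells, and the configured box loss
(SIoU default, CIoU/IoU selectable) with weight 2.

**Training at desk scale.**  The full-scale recipe (learning rate 0.01,
momentum 0.937, weight decay 5e-4, batch 16, 640 px input) is kept as the
documented `TrainConfig` default; the desk-scale `TrainConfig.smoke()`
regime is 128 px images, batch 4, 5 epochs.  Five epochs on 56 images are
~70 optimizer steps — far too few to fit a 7-way softmax from random
weights by any first-order method (measured: a standalone softmax reaches
only ~0.7 training accuracy in that budget).  `fit` therefore solves the
head in closed form first — ridge regression in the attention-gated
feature space, with ±2 logit targets for objectness and one-vs-rest
classes and encoded ground-truth offsets for the box rows — and the
epochs refine everything, attention block included, with the actual
detection losses under Adam at rate 0.005.  Prediction applies a low
score floor (0.05; trailing low-scored false positives do not reduce
area-based AP) and class-agnostic NMS: at this scale a neighboring cell
firing on the same object often disagrees about the class, and per-class
suppression would let that duplicate through as a high-ranked false
positive.

Problem sizes for the standard end-to-end run: 70 images (10 per class),
8:1:1 split, 128×128 px, 5 epochs — a complete generate–train–evaluate
cycle takes well under a minute on one CPU core.  With a 7-image test
split the mAP@0.5 estimate is quantized in steps of ~0.05 and varies by
roughly ±0.15 across seeds; the standard seeded fixture scores ~0.6–0.76.

## Known limitations

* The autodiff engine is deliberately minimal (no fused kernels, Python
  loop over depth-wise taps); it is sized for desk-scale maps, not for
  training at 640 px.
* The detector's features are hand-crafted; there is no learned backbone,
  so results on textured or low-contrast scenes degrade faster than a
  convolutional feature extractor would.
* The evaluator's one-vs-rest ROC construction is an explicit protocol
  choice; detection literature does not define a negative set, so AUC
  values are comparable only within this package.
* Rotated or 3-D boxes, GIoU/DIoU variants, COCO-JSON interop and
  per-size AP splits are out of scope.
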