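# Methods

This note records the models implemented in `addetr`, the conventions
and numerical choices behind them, and what the synthetic benchmark can
and cannot show.

## Problem setting

Crop-disease monitoring needs detectors that localize lesions — often
small, low-contrast, and visually similar to healthy leaf structures —
in RGB images, fast enough for field deployment.  The package
implements the components of a real-time detection transformer
specialized for this setting: a multi-scale aligning backbone, a
spatial–spectral encoder neck, and an IoU-family regression loss with
an inner-box criterion and a non-monotonic focal weight.  All neural
components run on a small reverse-mode automatic-differentiation engine
over numpy (`addetr.nn`), which keeps the package dependency-light and
every gradient checkable against finite differences.

## Bounding-box regression: the IPIoUv2 family

Boxes are parameterized as (xc, yc, w, h).  For a predicted box and a
ground-truth box (subscript *gt*):

* **Edge-distance penalty.**
  `p = ¼ (dw1/w_gt + dw2/w_gt + dh1/h_gt + dh2/h_gt)`, where dw1/dw2
  are the absolute left/right edge distances between the two boxes and
  dh1/dh2 the top/bottom ones.  The normalization by the ground-truth
  size makes p scale-invariant; p = 0 iff the boxes coincide.  We read
  the four d-terms as *corresponding-edge* distances (left↔left,
  right↔right, …): this is the only assignment under which p vanishes
  exactly at coincidence.
* **PIoU loss.** `L_PIoU = (1 − IoU) + 1 − exp(−p²)`, bounded in
  [0, 2].
* **Focal reweighting.** `q = exp(−p) ∈ (0, 1]`,
  `u(x) = 3x·exp(−x²)`, and `L_PIoUv2 = u(λq)·L_PIoU` with λ = 1.3 by
  default.  u is non-monotonic: both nearly-converged pairs (q → 1)
  and hopeless pairs (q → 0) are down-weighted, concentrating gradient
  on medium-quality samples.
* **Inner IoU.** Auxiliary boxes share the originals' centers with
  widths/heights scaled by γ (default 0.7); their IoU is a stricter
  overlap criterion for γ < 1.  The auxiliary intersection is clamped
  at zero when the scaled boxes are disjoint (the raw product formula
  would otherwise go negative), and γ = 1 recovers the plain IoU
  exactly.
* **Combined loss.** `L_IPIoUv2 = u(λq)·(2 − exp(−p²) − IoU_inner)`.
  It is zero iff the boxes coincide and differentiable in the predicted
  box everywhere the boxes are non-degenerate.  No upper bound is
  asserted for the combined loss.

Numerical conventions: the public scalar API rejects boxes with
non-positive width/height (`InvalidBoxError`); the training path
epsilon-clamps them (eps = 1e−7) so early-training gradients stay
finite.  In float64, `exp(−p)` underflows to exactly 0 once p ≳ 745;
the analytic ranges (q > 0, strict positivity of the combined loss for
distinct boxes) therefore hold wherever the quantities are
representable, which the tests state explicitly.

The GIoU/DIoU/CIoU/EIoU/SIoU/WIoU baselines in `addetr.losses`
implement external formulas from their original publications and exist
only for the loss-comparison harness.

## AFA and the MSANet backbone

The backbone (stride-4 HGStem; three DWConv + C2f stages at strides
8/16/32; batch norm + SiLU throughout) emits a three-level pyramid.
The AFA block fuses adjacent-stage features: 1×1 projections into a
common channel space; concatenation; a 3×3 gate convolution with
sigmoid producing two spatially-varying gates (channel split); and a
convex combination `λ₁·(w₁⊙x̂₁) + λ₂·(w₂⊙x̂₂)` followed by a 1×1
output projection.  λ₁, λ₂ are parameterized as the softmax of two
logits, so λ₁ + λ₂ = 1 and λᵢ ∈ [0, 1] hold *by construction* at every
optimization step; logits start at (0, 0), i.e. λ = (0.5, 0.5).  The
lower-resolution input of each fused pair is upsampled to the higher
resolution by nearest-neighbor interpolation before fusion.  Stage
widths/depths are configuration-driven; the default "small" profile
targets CPU training.  A plain residual baseline backbone with heavier
default widths provides the non-aligned comparison point; under the
default configuration the aligned backbone has strictly fewer
parameters.

## SSAFF encoder neck

### FTD — Fourier-transform downsampling

Per channel: 2-D FFT → centered truncation to the H/2 × W/2
low-frequency block → element-wise multiplication by a learnable
complex filter → inverse FFT, real part.  Conventions:

* **Scaling.** The output is scaled by (H/2·W/2)/(H·W) = ¼ so a
  constant input with the identity filter maps to the same constant
  (DC preservation).  This is the testable normalization; nothing else
  pins it down.
* **Filter.** One complex filter per channel, stored as independent
  real and imaginary parts, initialized to (1, 0): training starts as
  pure anti-aliased downsampling.  Taking the real part of the inverse
  transform is algebraically identical to symmetrizing the filter over
  conjugate frequency pairs, so the output is real for any filter
  values.  Filters are bound to the spatial size at first use
  (deterministic identity init, no randomness); feature maps of a new
  size lazily create a new filter.
* **Backward pass.** The operation is linear in the input (fixed
  filter) and in the filter (fixed input); the custom backward applies
  the analytic adjoints (fft/ifft with the matching index bookkeeping)
  and is verified against central finite differences.
* **Anti-aliasing.** Truncation removes all energy above the new
  Nyquist rate; a pure above-Nyquist tone maps to (numerically) zero,
  whereas strided subsampling folds it to an alias.  Odd spatial sizes
  are rejected (inputs are multiples of 32 in this architecture).

The analysis utilities `dft2`/`idft2` use the convention with the
1/(H·W) factor on the forward transform (DC coefficient of a constant
equals the constant); `freq_conv_oracle` combines the normalized
transform of the signal with the unnormalized transform of the kernel
so that the spectral product inverse-transforms to the plain circular
convolution — the convolution-theorem oracle used in tests.

### HA — hierarchical-aware patch weighting

The input is tiled into non-overlapping p × p patches.  Each patch's
descriptor is its channel-wise mean (a C-vector): the descriptor must
live in the same space as the task embedding ξ ∈ R^C and the channel
matrix P ∈ R^{C×C} for the weighting `t̂ᵢ = P·sim(tᵢ, ξ)·tᵢ` to be
dimensionally consistent, and the channel mean is the simplest such
reduction.  `sim` is cosine similarity clamped to [0, 1] (negative
alignment = fully suppressed).  All pixels of a patch are scaled by its
score and channel-transformed by P; since the patches tile the map
exactly, recombination is lossless and the block with sim ≡ 1, P = I
is the identity map.

### MFI and the neck topology

MFI fuses two same-resolution inputs: 1×1 reductions → concat → 3×3
preliminary fusion (baseline features) → HA branches → 1×1 →
reparameterized 3×3 (RepVGG-style: 3×3 + 1×1 + identity branches at
training time, merged algebraically for deployment; equivalence is
unit-tested at 1e−5) → 1×1.  HA patch sizes are assigned per pyramid
level: a stride-8 map of a 32k-pixel input is 4k × 4k, so both p = 4
(global) and p = 2 (local) divide it; stride-16 maps only admit p = 2;
stride-32 maps get the baseline path only.  The neck runs intra-scale
self-attention (one post-norm transformer layer with fixed 2-D
sine/cosine positional encodings) on the deepest level, top-down
fusion with MFI replacing concat-fusion, and bottom-up fusion with FTD
replacing strided-convolution downsampling.  A "baseline" neck
(concat+conv fusion, strided-conv downsampling) and an "identity" neck
(lateral projections only) provide the ablation comparison points.

## Detector and training

A DETR-style decoder consumes the flattened multi-scale memory (tokens
carry sine/cosine positional plus learned level embeddings).  Queries
are learned embeddings with reference boxes initialized on a regular
grid.  Three choices speed up convergence at small compute, all
standard in the real-time-DETR family:

* **Iterative refinement** — each decoder layer predicts a delta on the
  (detached) reference logits; boxes are
  `sigmoid(inv_sigmoid(ref) + delta)`.
* **Locality prior** — cross-attention logits receive an additive bias
  `−d²/(2σ²)` between the query's current reference center and each
  token's position (σ tied to the reference box size, clamped to
  [0.08, 0.5] in normalized units), so queries look near their box
  from the first step.
* **Deep supervision** — Hungarian matching and the full loss are
  applied to every decoder layer's output and averaged.

Matching costs are classification (−p of the true class), L1, and
1 − IoU (weights 1/5/2); the IPIoUv2 term is used only as the
regression *loss*, not in the matching cost, where the plain IoU is
more stable.  Classification uses focal binary cross-entropy with
α = 0.75 (favoring the rare positives — a few lesions versus hundreds
of query-class slots) and γ = 2, normalized by the number of matched
pairs.  Optimization: AdamW, linear warmup (50 steps) then cosine
decay, gradient-norm clipping at 5.

Training runs in float32 (the loss-analysis API works in the dtype of
its inputs, float64 in the tests); model initialization is a pure
function of the configuration seed, and a fixed seed with
single-threaded execution reproduces losses bit-identically.

Two profiles exist: the full-scale defaults (200 epochs, batch 16,
lr 1e−4, 640×640 — the published protocol of the architecture family)
and the desk profile used by the tests and harnesses (160×160 images,
~300 training images, 30 epochs, batch 8, lr 4e−3, 3 decoder layers,
~0.3 M parameters), sized so a full smoke-training run fits in minutes
on one CPU core.

## Synthetic data

The generator renders leaf-like scenes: a green background with smooth
mottling and vein-like streaks (hard negatives), plus 0–3 lesions per
image drawn from five parametric motifs (spot, blotch, rust-pustule
cluster, elongated streak, ring spot) keyed to the class id.  Default
study conditions: 5 classes with geometrically decaying class weights
(mild imbalance, echoing real disease surveys), lesion areas 2–10 % of
the image, contrast 0.35–0.9, 10 % occlusion probability, 10 % healthy
images.  Boxes are recorded from the rendered mask extent, and every
motif's mask reaches its nominal box edges, so ground truth matches
the sampled geometry to pixel rounding.  Datasets are written as PNG +
YOLO-TXT (`class cx cy w h`, normalized, 0-based, six decimals) in
train : test : val = 7 : 1 : 2 proportions (test is the single part),
stratified by each image's primary class.

What the generator does **not** emulate: photorealistic leaf texture,
within-class appearance diversity, illumination and camera variation,
dense lesion clutter, label noise, and domain shift between datasets.
A detector that passes the synthetic benchmark has demonstrated that
the architecture, losses, matching and evaluator are correct and
trainable — not that it would reach comparable accuracy on field
imagery.

Augmentation (resize/scale, horizontal flip, color jitter, 2×2 mosaic
composition, rare-class oversampling) is implemented and tested but
disabled in the deterministic smoke-training profile.

## Evaluation

Per-class matching is greedy in descending score with an IoU threshold
(default 0.5): a detection is a true positive iff its label matches an
unmatched ground truth of that class at or above the threshold.  AP
uses the 101-point interpolation of the precision envelope (the de
facto convention behind mAP@50–95 reporting); mAP@50–95 averages mAP
over IoU thresholds 0.50 : 0.05 : 0.95.  Macro precision/recall are
unweighted class means at a configurable operating threshold (default
0.25); classes with ground truths but no predictions contribute
precision 0, classes with no ground truths are excluded.  For ranking,
detections are collected with a low score floor (0.01) so the PR curve
is fully populated; the operating threshold applies to P/R only.  The
confusion matrix (classes + background) deliberately matches
class-agnostically so inter-class confusion and background confusion
are both visible; rows are normalized where nonzero.

## Known limitations

* The desk-scale detector is ~0.3 M parameters at 160×160 — the
  published architecture's scale (tens of millions of parameters at
  640×640) is out of reach on one CPU, so absolute accuracy numbers are
  not comparable to GPU-scale results.
* FTD filters are size-bound; fully convolutional deployment across
  arbitrary sizes instantiates one filter per encountered size.
* The decoder head is the standard query-decoder of the family; no
  claim is made about further head-specific improvements.
* The rasterization IoU oracle is O(grid²) per pair; the vectorized
  separable-count variant (exactly equal on axis-aligned boxes) is used
  for large sweeps.
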