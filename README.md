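# addetr

Real-time detection-transformer components for crop-disease lesion
detection, implemented and tested at desk scale.

Plant-disease monitoring needs detectors that localize lesions — small,
irregular, low-contrast, and easily confused with healthy leaf veins —
in RGB images, fast enough for field devices.  This package implements
the building blocks of such a detector as a verifiable library:

* **IPIoUv2 box-regression loss** and its constituents.  With boxes in
  (xc, yc, w, h) form, an edge-distance penalty
  `p = ¼(dw₁/w_gt + dw₂/w_gt + dh₁/h_gt + dh₂/h_gt)` drives the
  predicted box toward the target; `L_PIoU = (1−IoU) + 1 − e^{−p²}`
  (bounded in [0, 2]); a non-monotonic focal weight
  `u(λq) = 3λq·e^{−(λq)²}` with `q = e^{−p}` concentrates gradient on
  medium-quality pairs (λ = 1.3); an inner IoU on center-preserving
  auxiliary boxes scaled by γ = 0.7 makes the overlap criterion
  stricter.  The combined loss is
  `L_IPIoUv2 = u(λq)·(2 − e^{−p²} − IoU_inner)`.
  GIoU/DIoU/CIoU/EIoU/SIoU/WIoU baselines are included for comparison
  harnesses.
* **MSANet backbone** with AFA (adapt-fusion-align) blocks: 1×1 channel
  alignment, sigmoid spatial–channel gating from the concatenated
  features, and branch coefficients constrained to λ₁+λ₂ = 1 by a
  softmax parameterization (initialized at 0.5/0.5).
* **SSAFF encoder neck**: MFI attention fusion with a hierarchical
  patch-weighting branch (patches scored by cosine similarity to a
  learned task embedding, clamped to [0, 1]), and FTD — a 2× Fourier
  downsampler that truncates the centered low-frequency block of the
  2-D DFT, applies a learnable complex filter (identity-initialized),
  and inverse-transforms.  Truncation removes all energy above the new
  Nyquist rate, so downsampling is anti-aliasing by construction; the
  convolution theorem (spectral product = circular convolution) is the
  test oracle.
* **DETR-style detector** (queries with reference boxes, Hungarian
  matching, focal classification + L1 + IPIoUv2 training), a
  **synthetic lesion-scene generator** with exact YOLO-TXT ground truth
  and 7:1:2 stratified splits, and a **full evaluator** (macro P/R,
  101-point mAP@50 and mAP@50–95, background-aware confusion matrix).

Everything runs on a small numpy automatic-differentiation engine
(`addetr.nn`) — no deep-learning framework required — so every gradient
is finite-difference-checkable and the whole stack trains on one CPU.

## Worked example: the loss family

```bash
addetr losses-demo
```

```
pred = (6.0, 5.0, 4.0, 4.0), gt = (5.0, 5.0, 4.0, 4.0), lambda = 1.3, gamma = 0.7
IoU             0.600000
PIoU penalty p  0.125000
L_PIoU          0.415504
L_PIoUv2        0.383483
IoU_inner       0.473684
L_IPIoUv2       0.500064
```

Reading the numbers: the two 4×4 boxes overlap at IoU 12/20 = 0.6; the
left and right edges are each 1 px off, so p = ¼(¼+¼) = 0.125; the
penalty adds `1 − e^{−p²} ≈ 0.0155` to the IoU loss; the focal weight
`u(1.3·e^{−0.125}) ≈ 0.923` slightly de-emphasizes this (fairly easy)
pair; the γ-scaled auxiliary boxes overlap at only 0.474, so the
combined loss `0.923·(2 − 0.9845 − 0.4737) ≈ 0.5001` penalizes the pair
more than plain `1 − IoU = 0.4` would.

## Worked example: fitting the detector

```python
from addetr.config import desk_profile
from addetr.model import DetectionModel

config = desk_profile(seed=0)
config.data.total_images = 143      # 100 train / 29 val, quick demo
config.train.epochs = 10
results = DetectionModel(config).fit()
print(results.summary())
```

```
Detection model fit
==========================================================
backbone                                            msanet
neck                                                 ssaff
regression loss                                    ipiouv2
parameters                                         293,693
config hash                                   f588a0d3551f
train / val images                                100 / 29
epochs                                                  10
wall time [s]                                         80.3
----------------------------------------------------------
loss (first -> last)                      7.0715 -> 2.4767
precision                                           0.2590
recall                                              0.2024
map50                                               0.1119
map50_95                                            0.0208
==========================================================
```

Ten epochs on 100 images is just the beginning of convergence (the
loss is still falling).  The desk profile proper — 300 training
images, 30 epochs — reaches mAP@50 above 0.6 on the held-out synthetic
split in about ten minutes; that run is executed verbatim by the test
suite.  `results.predict(image)` returns scored, class-labeled boxes,
and `results.save(path)` / `DetectionResults.load_weights(path)`
round-trip the weights.

Shell equivalents: `addetr synth | train | eval | detect | ablate |
compare-losses` (see `addetr --help`); YAML configurations round-trip
through `addetr.config.load_config` / `save_config`, with the
full-scale training defaults (200 epochs, batch 16, AdamW at 1e-4,
640×640) available alongside the desk profile.

## Layout

| module | contents |
|---|---|
| `addetr.losses` | IPIoUv2 family + baseline IoU losses, stress sampler |
| `addetr.boxes` | box types, conversions, rasterization IoU oracle |
| `addetr.backbone` | HGStem, C2f, depthwise-separable convs, AFA, MSANet |
| `addetr.encoder` | DFT utilities, FTD, HA, MFI, RepConv, AIFI, necks |
| `addetr.detector` | decoder, Hungarian matching, training step, detect |
| `addetr.synth` | scene generator, YOLO-TXT/COCO I/O, augmentation |
| `addetr.metrics` | matching, macro P/R, AP/mAP, confusion matrix |
| `addetr.model` | `DetectionModel` / `DetectionResults` facade |
| `addetr.harness` | ablation grid and loss-comparison harnesses |
| `addetr.cli` | `addetr` command-line interface |
| `addetr.nn` | numpy autodiff engine, layers, optimizers |

See `docs/methods.md` for the models, conventions, and the design
decisions behind them.
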