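# Methods

## Problem and model

The package segments LSIL+ lesion regions in colposcopic
post-acetic-acid images. The pipeline assumes exactly one cervix per
frame, annotated with a rectangular box, and lesion regions annotated as
closed polygons with an LSIL or HSIL+ label. The lesion region is the
positive class; everything else (including benign acetowhite
metaplastic epithelium) is negative.

**Detector.** A two-stage anchor-based detector on images resized to
`input_side` (default 128). Backbone: four stride-2 conv-BN-ReLU blocks
to a stride-16 feature map. Stage 1 predicts per-anchor objectness and
box deltas (standard center/log-size parameterization); anchors cover
scales {0.30, 0.45, 0.60} of the input side at aspect ratios {1.0, 1.4},
matching the geometry of a cervix that dominates a 4:3 frame squashed to
a square. Stage 2 pools each proposal with ROI-Align (one bilinear
sample per bin at the bin center, 5×5 bins, no coordinate quantization)
and refines objectness and box. There is no classification branch:
"cervix" is the only category. Training: positives at anchor IoU ≥ 0.5
(or the best anchor), negatives below 0.3 sampled ~3:1, binary
cross-entropy on objectness, smooth-L1 (β = 0.2) on deltas, proposals
augmented with a jittered and the exact ground-truth box. Inference:
top-20 proposals, NMS at IoU 0.5, top-5 refined, the single best box is
returned if its score exceeds the objectness floor (0.5); otherwise the
detector falls back to the full-image box, so downstream stages always
receive a valid region.

**CLS-Net.** `feature1` and `feature2` are defined *structurally* as the
last encoder maps at strides 16 and 32 (robust to any layer-numbering
convention). The ASPP block has six branches — 1×1 conv, four 3×3
dilated convs at rates {2, 4, 6, 8} with padding preserving spatial
size, and global average pooling broadcast back to the grid — each
followed by BN + ReLU (the pooling branch by ReLU only, since a 1×1
spatial map starves batch statistics); the concatenation is projected by
a 1×1 conv-BN-ReLU to half the input channels. The rates are chosen so
the effective kernels (5/9/13/17) span the 20×20 stride-32 map of a
640×640 input. Fusion is additive, which forces equal widths: feature1
is projected by 1×1 conv + BN (no activation) to the ASPP output width.
The class projection (1×1 conv) sits *before* the final ×16 bilinear
upsample — cheaper and standard; the paper-scale alternative (after) was
not implemented. The head is a sigmoid for the default single
lesion-vs-normal class, per-pixel softmax for ≥ 2 classes. Binarization
uses a strict `prob > 0.5` rule (an exact 0.5 is background).

`fusion_scale` ∈ {1/16, 1/8, 1/4} reproduces the cross-layer ablation:
shallower settings add further ×2 upsampling stages fused with
projections of the stride-8/stride-4 encoder maps (80×80 / 160×160
planes at full scale). The default is 1/16, which is the configuration
that works best; the alternatives exist for the heatmap ablation panel.

**Encoders.** `efficientnet-b3`: stem + MBConv stages with B3
widths/depths (24×2 k3, 32×3 k3 s2, 48×3 k5 s2, 96×5 k3 s2, 136×5 k5,
232×6 k5 s2, 384×2 k3), squeeze-excitation at ¼ of block input
channels, swish activations; only layers up to the last stride-32 block
are instantiated. ImageNet pretraining is not required by anything in
the package. `tiny`: five stride-2 conv-BN-ReLU stages (8/16/24/32/48
channels) with the identical stride contract, used for CPU-scale
training and all learning tests.

## Training protocol

Soft Dice loss with smoothing ε = 1e-6 (differentiable; equals 1 − Dice
on binary inputs). Adam with lr 0.001, weight decay 1e-4 (L2-in-grad),
50 epochs, batch 16 at full scale; the lr is multiplied by 0.1 at epoch
20 — the protocol's schedule sentence is ambiguous, and ×0.1 is the
reading we implement (both factor and epoch are configurable).
Validation Dice/Recall are computed on binarized predictions per image;
`Score = (Dice + Recall)/2`; the checkpoint with the highest validation
score is kept, ties broken by the later epoch. The 7:1:2 split assigns
⌊n/10⌋ items to validation, 2·⌊n/10⌋ to test and the remainder to
training after a seeded shuffle — this reproduces the documented
partitions (5,455 → 3,820/545/1,090; 1,000 → 700/100/200) exactly,
which a plain ⌊0.7·n⌋ rule does not.

## Metrics

All five pixel metrics derive from per-image confusion counts; the set
report is mean ± population (÷ n) std over images, except accuracy,
which is pooled over all pixels (matching how such tables print accuracy
without an interval). Zero-denominator policy: empty truth and empty
prediction score 1.0 (dice/recall/precision); empty truth with a
nonempty prediction leaves recall undefined and the image is excluded
from the recall mean. The protocol only evaluates images with nonempty
truth, so the policy is a robustness measure. HR bins are half-open on
the left, (0.9, 1.0] … (0, 0.6], with hr = 0 closed into the lowest bin
so the bins are exhaustive; percentages are rounded to 2 decimals.

## Synthetic scenes

The generator emulates the *geometry and annotation format* of a
clinical colposcopy dataset, not its appearance statistics: a 4:3 canvas
(default 2,656 × 1,992), one bright pinkish elliptical cervix with a
darker os on a darker vaginal-wall background, lesions as irregular
harmonic-perturbed blobs whitened toward acetowhite (HSIL+ with stronger
contrast than LSIL — a rendering convention, not a biological claim),
speckles that are near-white and unsaturated, and gray/red rectangular
distractors strictly outside the cervix box. 20 % of scenes (default,
`confuser_prob`) receive an unlabeled whitish confuser blob inside the
cervix, emulating metaplastic epithelium. Generation is a pure function
of the spec including its seed.

Consequences for interpretation: passing tests demonstrate that the
pipeline's mechanics (detection, cropping, learning, metrics, mapping)
work end-to-end and that the networks can learn separable acetowhite
texture; they say nothing about performance on real colposcopic images,
whose lesion boundaries, lighting, bleeding and mucus have no synthetic
counterpart here.

Polygon rasterization uses the even-odd (parity) rule evaluated at
pixel centers (c + 0.5, r + 0.5); LabelMe files are written with
`shape_type: rectangle` (two corners) for the cervix box and accepted
back as either a rectangle or a 4-vertex polygon, since annotation
tools differ.

## Numerical choices

- All tensors float32; convolution is evaluated per kernel tap with
  BLAS-backed contractions (memory-light at these sizes).
- Bilinear resizing uses the half-pixel-center convention everywhere
  (resize, ROI-Align, heatmap upsampling); masks are restored with
  nearest-neighbor so they stay binary.
- Overlay blending rounds half-up to 8 bits; lesion pixels are copied,
  never recomputed.
- Heatmaps min–max normalize per panel; a constant plane maps to all
  zeros (bottom color). Channel reduction defaults to the mean, with
  max as an option.
- Batch normalization uses momentum 0.1 and ε = 1e-5; evaluation mode
  uses running statistics.

## Desk-scale problem sizes

The tests run the full pipeline at sizes a CPU handles in seconds to
minutes, chosen once as the package's study conditions: synthetic
scenes at 512 × 384 (4:3), segmentation at input side 128 (the pinned
8-image convergence run) or 192 (the single-image capacity test, which
needs the fused grid at the same resolution-relative-to-lesion regime
as the full-scale 640 → 40 × 40 configuration), detector at input side
128 trained for 10 epochs on 200 scenes. The full 640 / batch-16
configuration shares the identical code path and is exposed through the
CLI (`--size`, `--batch`).

## Known limitations

- No data augmentation (none is part of the protocol).
- The numpy backend is single-process; full-scale 640×640 training is
  possible but slow — the package's purpose at that scale is
  correctness, not throughput.
- The detector's backbone and anchor hyperparameters are package
  choices; the documented contributions are the deleted classification
  branch and ROI-Align pooling, and no attempt is made to mirror any
  particular original backbone.
- `evaluate_set` std is over images; std over repeated training runs is
  out of scope.
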