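# Methods

This note documents the models, procedures and numerical choices behind
`rdaunet`: what each stage of the pipeline computes, which parameters matter,
and what the synthetic phantoms do and do not establish.

## Problem setting

The package targets slice-wise binary segmentation of abdominal CT: given a
2D slice of Hounsfield-unit (HU) radiodensities, predict a per-pixel mask of
a bladder-like organ, or of lesions inside it. Organ and lesion are treated
as two independent single-class problems — two separately trained networks
with a single sigmoid output channel each — rather than one multi-class
model.

## Preprocessing

**Windowing.** A display window `[hu_low, hu_high]` is mapped affinely onto
`[0, 1]` with clamping: `out = clip((hu − lo)/(hi − lo), 0, 1)`. The default
is the standard abdominal soft-tissue window, level 40 / width 400
(−160..240 HU), exposed in `WindowSpec`. Windowing is monotone in HU and
idempotent under a subsequent (0, 1) re-window.

**Storage conventions.** HU slices round-trip through 16-bit PNGs with a
fixed offset (stored = HU + 1024), which covers the full −2048..4096 HU
domain losslessly; DICOM input applies rescale slope/intercept. Masks are
8-bit PNGs with {0, 255} ↦ {0, 1}.

**Resizing.** Images are resized 512→224 (or any target side) with bilinear
interpolation; masks with nearest-neighbour, which preserves binarity
exactly. A QC overlay renders the mask contour over the windowed image and
reports the fraction of mask foreground whose intensity exceeds a threshold
(default 0.1) — a cheap flag for annotation/image mismatches.

**Splits.** Train/validation splitting shuffles with a seeded generator and
assigns the first `floor(ratio·n)` items to training (default ratio 0.8).
The split is per-slice; callers wanting leakage-free per-patient splits can
group upstream and split the groups. Same seed ⇒ identical membership.

## Augmentation

Five transforms, each drawn independently and uniformly from its range:
scaling from the discrete choice set {1.0, 1.2}; rotation within ±15°;
x/y translation within ±10 px; horizontal shear within ±5°; horizontal flip
with probability 0.5. A draw is composed into **one** affine map in the
fixed order scale → rotate → shear → shift → flip, all about the image
centre, and applied identically to image (bilinear, zero fill) and mask
(nearest-neighbour, zero fill); output size is unchanged, so the 1.2×
scaling is centre-anchored with an implicit crop. Shift ranges are in the
current working resolution. Expansion emits each original plus
`multiplier − 1` augmented copies; the default multiplier 3 triples a
712-slice corpus to 2,136. Augmentation is applied after splitting by
default, so no augmented copy of a validation slice can reach training.

Design choices made where several readings were possible: the scale option
set is discrete (original vs 120%) rather than a continuous range; the
composition order is fixed for reproducibility; out-of-frame regions are
filled with background rather than reflected, to avoid fabricating tissue.

## Network

A five-level encoder–decoder. Encoder stages 1–2 are residual blocks, 3–5
are dense blocks; every stage ends in 2×2 max pooling (five spatial
reductions). Decoder stages mirror them with learnable 2×2-stride-2
transposed convolutions; each skip passes through an additive attention
gate, is concatenated with the upsampled decoder state, and fused by a 3×3
convolution; a final 1×1 convolution + sigmoid yields the probability map.
Inputs whose sides are not multiples of 32 are zero-padded and the output
cropped back.

Block semantics:

* **ResBlock(cin→cout):** conv3×3–BN–ReLU, conv3×3–BN, elementwise add of
  the block input (1×1 biased projection when widths differ), ReLU.
* **DenseBlock(cin, L, g):** L layers of conv3×3–BN–ReLU, each producing
  g channels and consuming the concatenation of the input and all previous
  layer outputs; output width cin + L·g. A transition conv (3×3) then sets
  the stage width before pooling.
* **Attention gate:** skip and gate are projected by biased 1×1 convs to an
  inner width (half the skip width), summed, ReLU'd, projected to one
  channel and squashed by a sigmoid into coefficients in [0, 1] that
  multiply the skip. The gate signal is the upsampled decoder state, already
  at skip resolution, so no internal resampling is needed.

Convolutions immediately followed by batch normalisation carry no bias (the
BN shift subsumes it); standalone convolutions (projections, gate
projections, output head) are biased. Weights are He-normal initialised
from a seeded generator, so builds are bit-reproducible.

**Default configuration and the parameter fingerprint.** The published
design fixes the block structure but not channel widths, dense depth or
growth rate; the only architectural fingerprint available is the total
trainable parameter count, 13,053,861. The default configuration was
therefore calibrated by exact search over schedule families (base width ×
doubling-with-cap schedules × dense depth × growth × transition kernel ×
decoder fusion depth), solving for the bottleneck width in closed form —
the total is piecewise-quadratic in any single width, with branches by
residue class mod 4 because the gate inner width is ⌊w/2⌋. The first exact
match inside the schedule family was frozen:

| level | kind  | width |
|------:|-------|------:|
| 1     | res   | 24    |
| 2     | res   | 48    |
| 3     | dense | 96    |
| 4     | dense | 96    |
| 5     | dense | 697   |

with 3 dense layers per block, growth rate 12, 3×3 transition, one fusion
conv per decoder stage. `count_parameters` verifies the total and prints the
per-stage breakdown; the count is independent of input size (the network is
fully convolutional). Other exact matches exist outside the doubling-with-cap
family; the shipped one is simply the first found in the preference-ordered
search. The odd bottleneck width is a consequence of demanding an exact
integer match, not a modelling statement.

`NetConfig.reduced(base_width)` scales the same topology down
((1, 2, 4, 4, 8)×base) for CPU-scale experiments.

## Numerics: the autodiff engine

No GPU framework is used; `rdaunet.nn` is a self-contained tape-based
reverse-mode autodiff over float64 numpy arrays, providing exactly the
operators the network needs. Convolutions are im2col + BLAS matmul; the
input-gradient of a stride-1 'same' convolution is computed as a convolution
with the flipped, channel-transposed kernel, keeping backward on the same
fast path. The 2×2-stride-2 transposed convolution has non-overlapping
output patches, so both directions are einsums. Max pooling breaks ties by
routing gradient to the first maximum in each window. Batch normalisation
uses batch statistics in training (momentum 0.1 running updates, unbiased
variance for the running estimate) and running statistics in evaluation;
eps 1e−5. Binary cross-entropy is computed on clipped probabilities
(1e−7), the standard guard for sigmoid-output networks. Two memory choices
keep the tape small: im2col buffers are recomputed during backward rather
than cached at forward time (they would otherwise dominate the tape), and a
`no_grad` context disables tape construction entirely for evaluation and
prediction passes. Gradients of the
assembled network are verified against central finite differences in the
test suite; agreement is at working precision except at isolated
ReLU/max-pool kinks, which any finite-difference probe of a piecewise-smooth
loss will graze.

## Training

Adam (β₁ 0.9, β₂ 0.999, eps 1e−8), learning rate 10⁻³, batch size 8,
binary cross-entropy on the sigmoid output (soft-Dice and BCE+Dice
selectable), seeded shuffling each epoch, no learning-rate schedule and no
early stopping. Defaults run 200 epochs for the organ task and 100 for the
lesion task. Per-epoch history records loss and pixel accuracy (at the 0.5
prediction threshold) on both sets; the lowest-validation-loss weights are
restored at the end. Non-finite loss aborts with a diagnostic. Checkpoints
embed the architecture config, and save→load→predict is bit-identical in
evaluation mode.

## Evaluation metrics

From per-pixel confusion counts: ACC = (TP+TN)/total,
DSC = 2TP/(FP+2TP+FN), IoU = TP/(FP+TP+FN), with the identity
DSC = 2·IoU/(1+IoU). The average Hausdorff distance is the symmetric mean
of the two directed average nearest-neighbour Euclidean distances between
foreground pixel centres, reported in pixels (no mm spacing is applied; a
boundary-pixels-only mode is available since the point-set and contour
formulations differ in general). ROC-AUC uses the rank/Mann–Whitney
formulation with ties counted half. Degenerate-input conventions: both
masks empty ⇒ ACC = DSC = IoU = 1; the distance is undefined (raised as
`UndefinedMetricError`) when either mask is empty, as is AUC for one-class
ground truth. All metrics are tested against brute-force oracles
(set-overlap arithmetic, all-pairs distances, exhaustive pairwise AUC
counting) to 1e−10 on random small masks.

## Phantoms

Each phantom slice is soft-tissue background (40 HU) with a smooth
low-frequency texture (±4 HU), one urine-filled organ region (10 HU),
optional lesions inside it (60 HU), bone (700 HU) only in the near-bone
taxonomy, and white Gaussian HU noise (σ = 8). Organ shapes: round,
elongated (aspect 1.8–2.6), irregular (low-order Fourier radial
perturbation), near-bone (ellipse clipped by a bone crescent), near-top.
Lesion patterns: none, single large, multiple large, small, irregular;
lesions are constructed inside the eroded organ so containment is
structural. Masks record exact pre-noise geometry. Organ area is drawn from
a fraction range (default 3–20% of the image). The noise default of 8 HU
keeps every pair of tissue means separated by more than 2σ (closest pair:
body vs lesion, 20 HU), so the tasks are learnable by construction, and at
zero noise/texture they are exactly solvable by HU thresholding — a failing
training run therefore indicates a pipeline bug, not an impossible task.

What phantoms do **not** emulate: partial-volume effects, reconstruction
artefacts, anatomical context (organs other than the single target),
contrast dynamics, or annotation noise. Passing the phantom benchmark shows
the pipeline is wired correctly and can fit a separable task; it says
nothing quantitative about clinical performance.

## The phantom benchmark

`rdaunet.benchmark.run_phantom_benchmark` generates 200 phantoms at 64×64,
splits 8:2, trains the reduced-width network (base 8, ~242k parameters) for
15 epochs with the standard recipe, and reports held-out Dice. These sizes
were chosen so the whole benchmark is a desk-scale computation; with the
default seed it reaches mean held-out DSC ≈ 0.97 (minimum per-slice ≈ 0.89),
comfortably clearing the 0.8 sanity bar, and attention coefficients remain
in [0, 1] throughout (they are sigmoid outputs by construction; the
benchmark asserts it on the observed maps).

## Known limitations

* CPU-only float64 training: fine at phantom scale, not intended for
  512×512 clinical corpora at full width.
* The parameter-count calibration admits multiple exact solutions; the
  shipped default is one principled member of that family.
* Per-slice splitting can leak patient-level information if slices from one
  patient appear in both sets; group upstream when that matters.
* The average-Hausdorff default uses all foreground pixels, not contours;
  the two conventions disagree on thick regions.
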