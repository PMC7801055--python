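# Methods

## Problem and scope

The package segments four diabetic-retinopathy lesion classes
(microaneurysm MA, hard exudate EX, soft exudate SE, hemorrhage HE) in
colour fundus photographs, pixel by pixel. Each class is trained as its own
binary problem by default (one sigmoid head; a multi-label head is
available via `ModelConfig.out_classes`), because the classes differ by
orders of magnitude in size and prevalence and are conventionally reported
separately.

## Network

Encoder-decoder with `depth` stride-2 stages (default 4) and
`base_channels` width at full resolution (default 16), doubling per stage.
The source architecture leaves depth and widths open; these defaults give a
sub-million-parameter model of the intended scale, and both are
configurable. Input height and width must be divisible by 2^depth.

**Downsampling** is a learned 3×3 stride-2 convolution + RReLU; no pooling
operator exists anywhere in the graph (global average pooling inside the
attention module is the one deliberate exception — it reduces to a vector,
not a coarser map).

**MSFF blocks** open with a 3×3 dilated convolution (dilation 2 — the
minimal nontrivial rate; the source states none) + RReLU, then three
splitting steps. Step *k* with C_k input channels keeps ⌊C_k/3⌋ channels
via a 3×3 convolution and passes C_k−⌊C_k/3⌋ on via a 5×5 convolution.
"Keep one third per step" admits several readings; the floor rule is used
because the retained widths plus the final pass-on then telescope back to
exactly the entry width (9+6+4+8 = 27 for C = 27), which matches the
block's channel-reduction intent and is asserted as an identity in the
tests. The concatenation is reduced by a 1×1 convolution and summed with an
identity residual (1×1-projected on channel mismatch), then rectified.
Blocks require ≥ 9 input channels so every third is nonzero, hence
`base_channels ≥ 9`.

**CCA fusion.** The lower-resolution decoder map is upsampled 2×
bilinearly (half-pixel-centre grid) and 1×1-projected to the skip width
*c*; the two attention vectors must be addable, which forces the equal
width. Each branch runs GAP → 1×1 conv + BN (squeeze to max(1, c/r),
r = 2) → RReLU → 1×1 conv back to *c*. The final 1×1 convolution restores
*c* channels because the gate must multiply *c*-channel maps. GAP is
applied after upsampling, following the printed operator order. The gate is
RReLU of the branch sum — faithful to the formulation even though an
unbounded gate is unusual; a sigmoid gate is available as
`ModelConfig.cca_gate="sigmoid"` for ablation. Both gated maps are
concatenated (2c channels) and refined by two 3×3 conv + RReLU layers.

**Activations and initialization.** All activations are RReLU with slope
bounds 1/8–1/3 (the standard interval from the activation literature),
sampled i.i.d. per element during training and fixed to the midpoint at
evaluation, so inference is deterministic. Convolution weights are
He-initialized (N(0, 2/fan_in)); biases start at zero, except the output
head (below).

## Loss

Balanced focal loss, per pixel: `w · |y − Q^γ| · BCE(Q, y)`, natural
logarithm, γ = 2, summed or averaged over pixels (mean by default for
training — the choice only rescales the learning rate). `w` is the ratio of
lesion pixels to all pixels in the training masks (`loss.w = "auto"`),
clamped to [1e-6, 1−1e-6]; an all-negative training set with "auto" is
rejected outright. The absolute value keeps the modulating factor
nonnegative for either label. Reference implementations of weighted
cross-entropy and the α-balanced focal loss are provided for comparison;
at γ = 0 the focal loss reduces exactly to cross-entropy.

Two numerical choices matter:

* Probabilities are clamped to [ε, 1−ε], ε = 1e-7, before any logarithm —
  but with a *straight-through* clamp (clip forward, identity gradient).
  A hard clamp zeroes the gradient of saturated predictions, which in
  practice lets the network collapse to all-background and never recover;
  with the straight-through form confidently wrong pixels keep a
  corrective gradient.
* The output-head bias is initialized to the lesion-prevalence logit
  log(π/(1−π)) (clamped to [1e-4, 0.5]) at the start of training
  (`TrainConfig.head_bias_prior`, on by default). This is the standard
  companion to focal-style losses on rare-positive tasks: it starts the
  predicted background rate near the true one instead of at 0.5, so early
  epochs are not spent un-learning a miscalibrated prior.

## Preprocessing

Order: crop → denoise → CLAHE → normalize, following the enumeration of
the steps; the source does not state whether denoising precedes cropping.

* **ROI crop.** Otsu's threshold on the luminance channel (the channel is
  unstated in the source; luminance is the defensible choice), foreground =
  above threshold, largest 8-connected component = field of view. Constant
  images are rejected as degenerate.
* **Denoise.** Normalized 3×3 Gaussian kernel with σ = 0.8 (the source
  fixes only the kernel size).
* **CLAHE** on the L channel of CIELAB, tile grid 8×8, clip limit 0.02 on
  scikit-image's normalized scale (the OpenCV-style parameterisation
  `clipLimit=2.0` has a different unit; the algorithm is the same).
  Defaults are configurable.
* **Normalization** x_norm = (x − μ)/θ with per-channel μ, θ pooled over
  the *training* images only and reused at test time — computing them over
  "all samples" would leak the test set.
* **Augmentation**: horizontal flip p = 0.5, rotation ±15°, shift ±10 %,
  rescale 0.9–1.1 (ranges unstated in the source; these are common mild
  defaults), applied identically to image and mask, mask resampled
  nearest-neighbour so it stays binary.

## Tiling and inference

Windows of 256 px at stride 64 (so interior pixels fall in 16 windows);
offsets enumerate all stride multiples plus an edge-flush offset per axis,
so coverage is total and boundary pixels are averaged over however many
windows actually contain them (1–15) — consistent with interior averaging
rather than a special boundary rule. Tiles with field-of-view coverage
below `min_roi_fraction` (default 0.5; no figure is stated in the source)
are dropped. At merge time *probabilities* are averaged (the
information-preserving choice; the source does not say whether labels or
probabilities are averaged) and thresholded at 0.5; pixels covered by no
valid tile are NaN sentinels, never silent zeros. Coordinates are 0-based
and half-open throughout.

## Training

Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 2e-3. The source prints
the rate as "2 × 10³", an evident sign typo — a rate of 2000 diverges
immediately. When the optimized loss stops decreasing for
`plateau_patience` epochs (default 5; only the factor is stated in the
source) the rate is divided by 10, with a relative improvement threshold
of 1e-4 and a floor of lr_init/100 — i.e. the factor-of-10 reduction is
applied at most twice, as in a typical 100-epoch schedule. The schedule
watches the epoch-mean *training* loss — "the loss" being optimized —
because a validation loss measured on few tiles is noisy enough that a
plateau rule on it decays the rate to zero long before convergence;
validation loss still selects the retained checkpoint. When the training
set fits in a single batch the sampler yields it whole instead of
oversampling, so the monitored loss is not corrupted by batch-composition
noise. 100 epochs and batch size 64 by default. The validation
split is 20 % of tiles, stratified by contains-lesion (no validation
protocol is stated in the source); batches interleave positive and
negative tiles ~1:1 when both exist. The best-validation checkpoint is
retained. Fixed seeds fix initialization, data order, RReLU draws and
augmentation; bit-level reproducibility across BLAS builds is not promised.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
retinal anatomy: a bright warm-toned circular field of view on a black
border (radius fraction 0.45), mild radial vignetting and texture noise,
dark random-walk vessel-like curves, and one lesion class per image stamped
as anti-aliased discs (ellipses for HE) with class-dependent sign and
scale: MA dark 1–3 px, EX bright 5–15 px, SE pale 8–20 px, HE dark 6–18 px,
matching the clinical appearance ordering (MA ≪ EX/SE/HE). Lesions are
rejection-placed fully inside the disc without overlap, so a mask's
positive count equals an independent re-rasterization of the stored shape
parameters — the oracle the tests use. Gaussian pixel noise (σ = 5) is
added last so denoising has work to do. A dataset draw makes
round(n·negative_fraction) images lesion-free (default fraction 0.25; the
positive/negative ratio is unstated in the source). Everything derives
from one integer seed; identical configs are byte-identical.

What the generator does **not** model: optic disc and fovea, vessel
branching topology, illumination fields, camera optics, JPEG artifacts,
inter-patient variability. Passing tests therefore demonstrate that the
pipeline and optimizer are correct and that the network can learn
lesion-like contrasts — not clinical-grade performance on real fundus
images, which additionally requires the real data and GPU-scale training.

## Problem sizes in the test suite

Tests run the default study conditions wherever cheap (512×512 tiling
grids, 100-seed containment sweeps) and scale the expensive learning
checks to what the numpy backend handles comfortably: the overfit check
trains a depth-2, 9-channel model on eight 64×64 synthetic tiles for 200
epochs; the end-to-end pipeline check uses six 128×128 images, 64-px
windows at stride 32, and 12 epochs. These sizes are the package's own
test-design choice; all architecture and loss defaults are unchanged by
them.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; full-scale training
  (4288×2848 images, 100 epochs, batch 64) is out of its intended range.
* The printed 0.97 M parameter figure of the original model is not
  reproducible because per-stage widths are not recoverable; parameter
  count is therefore not a matched quantity.
* The hard-positive worked value of the loss computes to 0.2280; the
  source prints 0.227, a one-unit rounding difference in the last digit
  that is flagged in the tests rather than absorbed.
* RReLU gates in CCA are unbounded; training can be noisy at high learning
  rates (5e-3 diverges on the synthetic overfit task; 2e-3 is stable).
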