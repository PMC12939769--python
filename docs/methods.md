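# Methods

This note documents the models, algorithms and design choices in
`blastoseg`: what is computed, under which assumptions, with which
defaults, and what the synthetic phantoms do and do not demonstrate.

## Problem

Day-5 embryo (blastocyst) micrographs are segmented into five classes —
background (BG), zona pellucida (ZP), trophectoderm (TE), blastocoel
(BC, also written BL) and inner cell mass (ICM).  The images are
difficult for intensity-only models: inter-class contrast is low, ZP and
TE differ mainly in micro-texture, shapes vary with expansion stage, and
BC+BG pixels vastly outnumber the thin shells and the small ICM.  The
network here addresses this with a fixed multimodal input stem, a
parameter-frugal grouped-convolution encoder-decoder (≤ 0.65 M trainable
parameters at the native 400×400, five-class configuration), and a
class-volume-weighted Dice loss.

## Multimodal input stem

Each grayscale frame (normalized to [0, 1]) is decomposed into four fixed
channels before entering the network:

1. **Intensity** — the frame itself.
2. **Local binary pattern** — the classic 8-neighbor, radius-1 code:
   a bit is set when `neighbor >= center`, bits ordered clockwise from
   east, code divided by 255.  No uniform-pattern mapping is applied;
   the plain code keeps the operation self-contained and hand-checkable.
   Borders are reflect-padded.  LBP is invariant to additive intensity
   shifts, which decouples the texture cue from illumination.
3.–4. **Gabor responses at 0° and 90°** — absolute response to a
   zero-mean, even-symmetric (cosine-phase) Gabor kernel, min–max
   normalized per image.  Defaults: wavelength 8 px, envelope σ = 4 px,
   aspect ratio 0.5, kernel side `2*ceil(2σ)+1`; the mean is subtracted
   from the kernel so constant regions map to exactly zero.  The
   mid-frequency band matches the ripple scale of the TE/ZP rings at
   native resolution.

Orientation is represented as *two* channels (four channels total).
The alternative reading — one combined orientation channel — is
supported by configuring `StemConfig.orientations`; two channels are the
default because orientation selectivity is the point of the cue.  The
stem is fixed preprocessing, computed once per image, never recomputed
inside the network and never learned.

## Network

Channel widths are (32, 48, 64, 96) over the four encoder scales with
groups = 4 everywhere; the decoder mirrors them (96, 64, 32).  The widths
are a free choice — the published contract is the 0.65 M parameter
budget, which this configuration meets at 528,533 trainable parameters
(weights, biases and batch-norm scale/shift, counted exactly).

* **Stem fusion (FU-1)**: concat of the modality channels → 1×1 conv →
  BN → ReLU, at full resolution.
* **Encoder**: stride-2 3×3 conv (+BN+ReLU) then a dual-path grouped
  (DPG) block at each of 1/2, 1/4, 1/8 resolution; a final stride-2 conv
  (+BN+ReLU) is the compact bottleneck at 1/16 (25×25 for 400×400
  input).  No further downsampling — the small ICM would not survive it.
* **DPG block**: two grouped 3×3 convolutions of the same input with
  independently initialized weights, each followed by BN+ReLU, their
  concatenation fused by a 1×1 conv (+BN+ReLU).  The two paths are
  evaluated as one fused kernel call that shares the im2col expansion;
  this is bit-for-bit equivalent to two separate convolutions (tested)
  and roughly halves the dominant memory traffic.
* **Decoder**: transposed 3×3 stride-2 convolutions (output side exactly
  doubles: pad 1, output padding 1) restore 1/16 → 1/8 → 1/4 → 1/2 →
  full; a DPG block and a 1×1 squeeze sit after the first upsampling,
  and a final DPG block after the last.  Fusion units concatenate then
  blend with a 1×1 conv.
* **Semantic skips**: grouped 3×3 → BN → ReLU → 1×1 conv → BN → ReLU
  pathways carry (1) the deepest encoder DPG output into the 1/8-scale
  decoder fusion and (2) the stem-fusion output into the full-resolution
  fusion.
* **Head**: 1×1 conv to 20 channels, then a grouped 3×3 conv with 5
  groups (one group of 4 channels per class) to the 5 class maps, then
  channel softmax.  A grouped head with one group per class keeps the
  final stage grouped while producing exactly the five class channels;
  with groups = 4 elsewhere a 4-group head is impossible (5 is coprime
  with 4).

Ablation toggles: `use_mbi_stem=False` feeds the bare intensity through
the same fusion conv; `use_dpg=False` replaces each DPG block by a
*single* grouped path of matched output width (keeping parameter counts
comparable, so the ablation isolates the dual-path fusion rather than
raw capacity — an ungrouped conv of matched width would have ~1.4× the
block's parameters); `use_ssp=False` removes both skip pathways and
their fusion concats.

Weight init is He-uniform (bound `sqrt(6/fan_in)`) from a seeded
generator; BN starts at scale 1, shift 0; no pretrained weights anywhere.
Ties in the per-pixel argmax break toward the lowest class index.

## The numerics layer

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine on numpy (`blastoseg.nn`) with exactly the
operations the model needs — grouped/strided conv (im2col +
BLAS matmul), transposed conv, batch norm, ReLU, concat, channel softmax
and the generalized Dice loss.  All float32, NCHW.  Every primitive's
gradient is finite-difference checked in the test suite.  Adam follows
the standard bias-corrected form with β₁ = 0.9 and β₂ = the configured
squared-gradient decay.

## Training

Defaults: learning rate 0.001 (constant), squared-gradient decay 0.95,
L2 0.0005 applied to convolution kernels only (not biases, not BN —
keeps normalization statistics unbiased), 35 epochs, generalized Dice
loss with class weights `w_c = 1/(Σ_i g_ci)²` recomputed per batch.
A class absent from a batch has infinite nominal weight; it is given
weight zero for that batch so it cannot dominate, with ε = 1e-5 guarding
the final ratio.  The loss is bounded in [0, 1] up to ε and reduces to
1 − mean Dice when class volumes are equal.

Three training-loop choices that matter on small CPU runs:

* **Batch size 1.**  With few-epoch budgets the number of optimizer
  steps, not per-step gradient quality, limits convergence: shrinking
  the batch multiplies the steps at nearly equal epoch cost.  On the
  standard phantom check (64 train / 16 held-out, 128 px, 20 epochs)
  held-out mean Jaccard goes 0.57 (batch 4) → 0.68 (batch 2) → 0.89
  (batch 1 with the normalization below).
* **Per-sample normalization statistics at inference.**  With
  single-image batches, training normalizes every feature map by its own
  image's statistics; evaluating with exponentially averaged population
  statistics then mismatches the learned features badly (held-out JC
  0.39 vs 0.89 on the same weights).  The default inference mode
  therefore normalizes per sample and per channel (instance-norm
  semantics; batch-size independent and deterministic).  Classic
  running-stats inference remains available
  (``NetworkConfig(instance_norm_eval=False)``), and
  ``recalibrate_batch_norm`` can replace the running averages with exact
  dataset means for that mode.  The layer graph and parameter count are
  identical in both modes.  A side benefit on low-contrast imagery:
  per-image normalization removes global illumination offsets that
  otherwise mask the faint ICM/cavity intensity separation.
* **On-the-fly flip augmentation (default on).**  Each training sample
  is presented in one of the four flip states per visit.  Because LBP
  codes are not mirror-equivariant, the modality stacks of all four flip
  states are precomputed from the flipped *images* (not by flipping the
  channels).  This mirrors the geometric augmentation family used for
  the full pipeline at no dataset-size cost (measured +0.02 mean JC on
  the standard phantom check).

Validation (10% by default) is split by *source image*, so offline
augmented variants never straddle the split; the best-validation-loss
checkpoint is retained.  "Accuracy" in the recorded history is global
pixel accuracy (the fraction of pixels whose argmax matches the label);
it is recorded because it is the conventional second curve next to the
loss, though Jaccard is the metric that matters.

## Offline augmentation

The 16× expansion is the 4 × 4 grid {identity, horizontal flip, vertical
flip, both} × {identity, translation, crop-resize, translation+crop} —
the only orthogonal combination of the four named families that yields
exactly 16 variants (200 source pairs → 3200).  Translations are
integer-pixel with reflective fill (no fake "void" class); crop windows
(side fraction 0.7–0.95) are resized back to the source size, bilinear
for images and nearest-neighbor for masks, so masks never gain labels.
The originals are kept aside for validation splitting rather than
counted into the 3200.

## Phantoms

The real benchmark (235 Hoffman-modulation-contrast images) is
password-protected, so the package ships a generator of blastocyst-like
phantoms that reproduce the *challenges*, not the optics:

* Geometry: a randomized, gently dented ellipse; ZP annulus enclosing a
  TE annulus enclosing the BC cavity; one eccentric ICM disk inside the
  cavity, placed against the TE ring (found by ray-marching to the
  cavity edge and clipped to the cavity).  Shell thicknesses ≥ 2 px.
* Rendering: per-class base intensities separated by at most `contrast`
  (default 0.12, the low-contrast dial; TE sits 0.05·c from BG,
  ICM 0.35·c from BC); fine smoothed speckle on ZP vs angular "cellular"
  ripple on TE (the texture-similarity challenge LBP is meant to
  resolve); coarse blobs on ICM; smooth cavity; a linear illumination
  gradient (amplitude 0.08); additive Gaussian noise (σ = 0.02); clip to
  [0, 1].
* Statistics: BC+BG cover ≥ 55% of pixels (class imbalance); every
  draw contains all five classes and satisfies the anatomical adjacency
  (BG never touches BC); `expansion` < 1 shrinks the cavity and deepens
  the dents, emulating collapse.

What phantom results do **not** show: performance on real
Hoffman-modulation optics, real annotation noise, hatching or fragmented
embryos.  Passing the phantom suites demonstrates that the architecture,
loss, training loop and metrics are implemented correctly and that the
pipeline learns and degrades in the expected directions — not that the
published real-data accuracy is reproduced.

## Evaluation

Confusion counts are exact per-pixel tallies; JC and DSC follow the
formulas above, with pooled-counts aggregation over a test set by
default (per-image averaging available).  Classes with empty union are
excluded from means (avoids the arbitrary 0/0).  Confidence is the mean
softmax margin; the review-flag threshold is the 5th percentile
(linear-interpolation convention) of validation confidences, flag
strictly below.  Perturbations: Gaussian noise of a stated variance then
clip; salt-and-pepper by per-pixel Bernoulli hits at the stated density,
half salt half pepper; Gaussian blur of stated σ (reflect boundary).
The robustness sweep re-scores pooled mean JC per condition with a clean
baseline row.

## Scaled-down study sizes

CPU-scale checks use phantom sets far below the real protocol
(which trains 3200 augmented 400×400 images for 35 epochs on a GPU).
The learning-sanity run trains the default architecture at 128×128 on
64 phantoms for 20 epochs and scores 16 held-out phantoms; the ablation
comparison trains all six module-toggle combinations briefly at 64×64
across three seeds; the robustness sweep reuses the learning-sanity
model.  These sizes are the package's own test protocol and are stated
here so results are interpreted at their scale.

## Known limitations

* The phantom is a geometric cartoon; texture realism is limited.
* Blur perturbations can *raise* phantom Jaccard slightly at small σ
  because blurring suppresses the additive sensor noise the phantoms
  carry; the monotone-degradation property is therefore evaluated
  within each perturbation family (severity ordering), not against the
  clean baseline.
* Single-channel input only; no learnable stem; exactly two Gabor
  orientations.
* Training is single-threaded numpy: practical for the scaled-down
  protocol, not for 400×400 × 3200-image runs.
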