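# Methods notes

This note records how each stage of `octfluid` is modelled, the choices
made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Preprocessing chain

The chain runs histogram matching → median filter → CLAHE → gamma →
entropy ROI, with the edge map computed from the enhanced, cropped image
so that the network's two inputs stay pixel-registered (the attention
block multiplies their feature maps elementwise, which only makes sense
on registered grids).

* **Histogram matching** maps the image's empirical intensity CDF onto a
  user-supplied reference scan (delegated to
  `skimage.exposure.match_histograms`). The reference is always an
  explicit argument — pass `None`/`"self"` to skip — never chosen
  silently, so runs are reproducible from their logs.
* **CLAHE** uses a *relative* clip limit: per 8×8-grid tile, the 256-bin
  histogram is clipped at ℒ × (tile pixels / 256) with ℒ = 1.37, i.e.
  slightly above the uniform bin height, and the clipped excess is
  redistributed over the histogram's *occupied* bins before the CDF
  mapping; per-pixel output bilinearly blends the four surrounding tile
  mappings. Redistributing over the support (rather than all 256 bins)
  keeps the operation a genuine equalization for narrow histograms: a
  low-contrast tile is stretched across its own range instead of
  collapsing to the identity map. A constant image maps to a constant.
* **Entropy ROI**: base-2 Shannon entropy of the 256-bin histogram in a
  9×9 window; the minimal row band whose per-row mean exceeds 0.5 bits is
  kept, expanded by an 8 px margin. Row-band cropping (not free-form
  masking) matches the horizontal-band anatomy of B-scans. If no row
  passes, the full image is used and a warning logged — never an empty
  crop.
* **Edge filter ψ**: the antisymmetric linear operator is realized as a
  derivative-of-Gaussian pair at scale σ = τ = 1.8 px, truncated at
  ⌈3τ⌉, which is the canonical first-order (Taylor) edge operator;
  kernels are bitwise antisymmetric, so a constant image yields an
  exactly zero response. The two signed responses are combined by
  gradient magnitude and rescaled by the peak to [0, 1]; a peak below
  1e-9 (numerical dust on near-constant images) is treated as zero
  rather than amplified by the rescale. τ is exposed in
  `PreprocessParams` and the functional form is swappable.

All coordinates are 0-based, row-major, with half-open crop boxes.

## Network

A U-Net-shaped encoder–decoder with `n_stages` encoder stages (default 4;
channels `base_channels × {1,2,4,8}`, default base 32 — widths are not
dictated by the problem, standard doubling is used). Spatial dimensions
halve between consecutive stages (max-pool at stage entry), so stage *i*
operates at 1/2^(i-1) of the input resolution; the decoder mirrors this
with nearest-neighbour 2× up-sampling followed by a 3×3 convolution
(avoids the checkerboard artefacts of transposed convolution).

**Attention block.** Both inputs are convolved (3×3), multiplied
elementwise and passed through ReLU — the edge stream gates the image
stream. A small convolutional autoencoder (two stride-2 encodings down to
`bottleneck_ratio × channels`, default ¼, then two up-samplings back)
compresses and reconstructs the gated maps; a softmax **across channels**
turns the reconstruction into attention weights that sum to one at every
pixel — the one interpretive commitment of the block, since channel
softmax is the only axis that yields weights *over feature maps*.
Separable convolutions of the two raw inputs are multiplied by those
weights and concatenated (2 × channels outputs). Deeper stages receive
average-pooled copies of the raw edge map, the cheapest co-registered
multiscale edge signal.

**Inception/Residual block.** Parallel 1×1, 3×3, 5×5 convolutions and a
stride-1 3×3 max-pool branch (1×1-projected) are fused by elementwise
addition, then integrated by a 1×1 convolution and refined by a 2×2
convolution with asymmetric (0,1)×(0,1) padding (even kernels need an
explicit padding convention). A 1×1-projected shortcut joins **after**
the refinement, the canonical residual placement; this keeps the identity
path live even if every other kernel is zeroed.

**Normalization and initialization.** Instance normalization (per-sample,
per-channel over space) follows each convolution that feeds a ReLU, and
normalizes the separable-conv features before attention weighting.
Without it the multiplicative gating makes activation scale grow
quadratically through the stages and the sigmoid head saturates early in
training. Instance norm was chosen over batch norm because it has no
running statistics: inference is deterministic with no train/eval mode
distinction. Norm gains/biases are excluded from weight decay (the usual
convention). Convolutions use seeded He-uniform initialization (the
network is ReLU-dominant); the head bias starts at −3 so the sigmoid
begins near the sparse foreground prior (~5 % fluid pixels) instead of
0.5, which removes the early training phase that merely suppresses
background.

The head is a 1×1 convolution with one kernel per fluid class and a
sigmoid: channels are independent probabilities (multi-label), background
is *implied* by all classes falling below threshold rather than being an
output channel. `predict_mask` lets classes above threshold compete by
argmax, ties breaking to the lowest class index.

**Autodiff.** No tensor/autodiff library is part of the dependency set;
the package implements reverse-mode differentiation over numpy arrays
with exactly the operator set the network needs. Convolution is explicit
im2col + GEMM in both passes (the input gradient is a full correlation of
the zero-stuffed output gradient with the flipped kernel); every backward
rule is validated against central finite differences in
`tests/test_autodiff.py`. Forward/backward run in float32; the gradient
checks run the same code in float64.

## Training protocol

Combined loss `w_bce·BCE + w_dice·DiceLoss` with default unit weights
(no weighting is implied by "combined"); Dice uses ε = 1e-6 smoothing and
averages over classes with sums pooled over the batch; BCE clips
probabilities to [ε, 1−ε]. Targets are one-hot over the three fluid
channels; background contributes only through the negative BCE terms,
matching the multi-label head.

Adam (β = 0.9/0.999) at lr 10⁻³ with L2 10⁻⁴ applied to convolution
kernels only; batch 16; up to 100 epochs; validation after every epoch;
learning rate ×0.1 when validation loss fails to improve by more than
1e-4 (absolute — guards against float noise) for 5 consecutive epochs;
early stop after 10 unimproved epochs, restoring the best-validation
weights. Plateau patience, early-stop patience, the ±10° rotation range
and the [0.9, 1.1] intensity-jitter range are conventional defaults, all
exposed in `TrainConfig`. One master seed fans out deterministically:
split = seed+1, batch shuffling = seed+2, augmentation = seed+3; weight
init uses the same master seed.

`validate_on_train=True` removes the 80–20 split and validates on the
training set itself — the configuration used by the overfit diagnostic
(below), where generalization is deliberately not the question.

## Synthetic phantoms

Each phantom is a curved bright band (sinusoidal bowing, amplitude set by
`layer_curvature`, with faint internal layering) on a dark background,
carrying elliptical fluid pockets: IRF in the inner band, SRF just above
the lower boundary, PED as half-ellipse bumps that push the lowest
boundary downward. All pockets share one dark intensity, so class
identity is carried by position and shape only — a segmenter cannot
succeed by thresholding. Speckle is multiplicative clipped Gaussian,
`I·(1+σε)` with σ = 0.15 by default, the standard first-order OCT speckle
surrogate. Pockets are placed by rejection sampling (100 attempts, then a
`PlacementError` naming the class) with a 2 px separation halo so each
requested pocket stays its own connected component. Identical specs
regenerate bit-identical images.

What the phantoms do **not** emulate: realistic OCT speckle statistics
(correlated, Rayleigh-family), vendor-specific contrast and artefacts,
real retinal layer morphology, pathology co-occurrence, or 3-D context.
Passing the synthetic experiments therefore demonstrates that the
implementation is correct and trainable end-to-end — not that the
architecture reaches clinical accuracy; that claim would require the real
multi-vendor datasets and full-scale training, which are outside this
package's scope.

## Problem sizes of the shipped experiments

The end-to-end overfit diagnostic trains on 8 phantoms at 128×128 with
batch 4, lr 10⁻³ and at most 200 Adam steps, using a 3-stage network with
base width 8 (~160 k parameters): small enough to run on one CPU core in
minutes, large enough that the dual-input attention pipeline is exercised
at every stage. It reaches mean foreground Dice ≈ 0.98 across
IRF/SRF/PED. Shape contracts are checked on a 4-stage 256×256 build
(base width 16). Reproducibility is checked by regenerating datasets
byte-for-byte and re-running a short training twice (loss trajectories
agree to 1e-4; bitwise equality is not asserted because BLAS summation
order is platform-dependent).

## Numerical conventions and degenerate inputs

* Metrics: 0/0 ratios report 0 and are flagged degenerate; Dice of two
  empty masks is 1 (flagged); degenerate entries are excluded from macro
  averages. Dataset aggregation is micro (pooled pixel counts) by
  default, macro by flag — micro is threshold-stable for rare classes.
* ROC: descending threshold sweep over unique scores with tie groups;
  AUC by trapezoid; equals the Mann–Whitney statistic with ties at half
  credit (tested to 1e-9). Pixel-level, one-vs-rest per class.
* Constant images: histogram matching and input standardization reject
  them (undefined inverse CDF / zero variance); CLAHE and the edge filter
  map them to a constant and zero respectively.
* `predict_mask` threshold is (0, 1) exclusive; label masks are uint8
  PNGs with literal values 0–3.

## Known limitations

* CPU-only and modest problem sizes; no GPU path, no mixed precision.
* Instance norm makes each prediction independent of batch composition
  but also discards absolute intensity scale per channel; inputs are
  standardized anyway, so this is consistent, but networks trained here
  will not transfer to pipelines that skip standardization.
* The exact functional form the original edge operator and the ROI rule
  should take is underdetermined; the derivative-of-Gaussian reading and
  row-band entropy cropping are documented choices, both swappable via
  configuration.
* Checkpoints embed the architecture spec and refuse mismatched loads,
  but no backward-compatibility guarantees are made across versions.
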