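# Methods

## Problem and scope

`echoseg` segments lesions in 2-D grayscale breast-ultrasound images. The
three properties that make this modality hard — heavy multiplicative
speckle, low lesion/background contrast, and smooth intensity
nonuniformity — are reproduced by a synthetic phantom generator, so the
entire pipeline (preprocess → train → predict → evaluate) can be built,
trained and validated quantitatively without any clinical data. Nothing in
the package depends on a particular scanner or dataset; clinical images in
PNG/TIFF with paired binary masks drop into the same interfaces.

## Segmentation model

The network is a U-Net with three modifications.

**Residual level blocks.** Each encoder/decoder level computes
`u = c(v, w_h) + w v`, where `c` is two convolution → batch-norm → ReLU
layers and `w` is a 1×1 projection used when input and output widths
differ. Because `∂u/∂v = I + ∂c/∂v`, gradients cannot vanish through a
stack of such blocks — the motivation for using them on noisy,
low-contrast input where deep features are needed.

**Fused spatial–channel attention (SCAB).** Given features
`b ∈ R^(G×P×Q)`, a spatial gate `S ∈ [0,1]^(1×P×Q)` is computed from the
channel-wise max and mean maps through a k×k convolution and sigmoid, and
a channel gate `C ∈ [0,1]^(G×1×1)` from global max- and average-pooled
descriptors through a shared two-layer bottleneck MLP and sigmoid. The two
gated copies `b⊙S` and `b⊙C` are concatenated (2G channels) and projected
back to G channels by a 1×1 convolution. The back-projection is required
for the decoder's skip concatenation to type-check; the gate internals
follow the standard CBAM construction, the canonical realization of
"where to look" × "which features matter" attention.

**Residual SCAB (RSCAB).** `d_att = SCAB(conv1x1(d))`;
`out = conv1x1(Cat(d_att, d))`. The ungated input rides along through the
concatenation, so shallow attention is carried into deeper features.

Assembly: encoder of `depth` levels (residual block per level, 2×2 max
pooling between levels, channels doubling), each skip passed through SCAB
before concatenation into the decoder (2× bilinear upsampling +
channel-halving conv, then a residual fusion block), and a final 1×1
convolution + sigmoid yielding per-pixel foreground probabilities.
`attention="rscab"` additionally appends an RSCAB to each level block;
`"none"` gives a plain residual U-Net for ablations.

Numerical/architectural choices that were genuinely open:

- **Kernel size** defaults to 3×3. Even kernels (2×2, 6×6) are supported
  with "same" output size via top/left-heavy padding, selectable through
  `ArchConfig`, since descriptions of this architecture family sometimes
  use even kernels; odd kernels are the numerically cleaner default.
- **Normalisation/activation** inside blocks: batch-norm + ReLU after each
  convolution. Running statistics (momentum 0.1, biased variance) make
  inference batch-size independent and deterministic.
- **Down/upsampling**: 2×2 max pooling; 2× bilinear interpolation
  (half-pixel convention) followed by a 3×3 convolution.
- **Defaults**: depth 4, base 16 channels. The tested desk-scale
  configuration is depth 3, base 8 (~35k parameters), which trains to
  >0.9 validation Dice on default phantoms in minutes on one CPU core.

The numerical core is a small reverse-mode autodiff engine over float64
numpy arrays (`echoseg.autograd`) providing exactly the primitives the
model needs; every primitive's gradient is validated against central
finite differences, and every block against naive loop-based references.

## Losses

For per-pixel probabilities `p` and labels `t` over all N pixels of a
batch (micro-average):

- `BCE = -(1/N) Σ [t log p + (1-t) log(1-p)]`, with `p` clamped to
  `[1e-7, 1-1e-7]` so saturated predictions stay finite.
- `Dice = 1 - (2 Σ p t + s) / (Σ p² + Σ t² + s)` with smoothing constant
  `s = 1` (squared-denominator form); `s` keeps the empty/empty case
  defined (loss 0).
- Composite: `tau·BCE + Dice`, `tau = 1.5e-3`.

BCE alone is dominated by the background class when lesions are small;
Dice is insensitive to class imbalance but has a harsher optimisation
landscape. The small BCE term smooths optimisation without letting the
background dominate. The tests document this: appending agreed-empty
pixels leaves the Dice loss unchanged (in the small-smoothing limit) but
shifts BCE.

## Initialisation and optimisation

Convolution weights are drawn from N(0, 2/fan_in) with
fan_in = k² × input channels (the ReLU-preserving scaling); biases start
at zero. The optimiser is Adam: decay constants beta1 = 0.95,
beta2 = 0.999, learning rate 1.5e-4, denominator stabilizer 1.5e-8, with
standard 1/(1-betaᵗ) bias corrections. An alternative
`literal_correction` mode divides the moments by the decay constants
themselves and permits beta2 = 1.0 (which freezes the second moment);
it exists for side-by-side comparison and is not the default because it
is not a convergent Adam variant. Training shuffles with a dedicated
seeded generator, records per-epoch mean train loss and validation Dice,
and keeps the best-validation-Dice state; batch size defaults to 8.

## Preprocessing

Order: ROI crop → bilateral denoise → histogram equalization (the
capture → denoise → enhance order).

- **ROI** boxes are 0-based half-open rectangles, matching array slicing.
  In clinical use an operator draws the box so the lesion fills ~30% of
  it; `auto_roi_box` reproduces that convention from a known mask for
  synthetic work, and `roi_tumor_fraction` validates any box against the
  0.3 target.
- **Bilateral filter**: each output pixel is the spatial×range
  Gaussian-weighted mean of its in-bounds (2r+1)² neighbourhood. Defaults
  sigma_spatial = 3 px, sigma_range = 0.1 (for [0,1] images),
  r = ceil(3·sigma_spatial) — parameters are not standardised in the
  field, so all three are exposed in the config.
- **Histogram equalization** maps each of J (default 256) quantized gray
  levels to its empirical CDF value e_j = (1/c) Σ_{i≤j} c_i. The map is
  monotone (rank-preserving); a constant image maps to 1.0 (all mass in
  one bin).

## Evaluation indices

Dice `2|R∩G|/(|R|+|G|)` and IoU `|R∩G|/|R∪G|` on regions (the identity
dice = 2·iou/(1+iou) is asserted in tests); Hausdorff distance and mean
absolute deviation on boundaries. Boundaries are inner contours (a
foreground pixel with a background 4-neighbour); distances are Euclidean
in pixel units. HD is the standard min-inner/max-outer form — the
farthest nearest-neighbour distance, symmetrised; MAD averages the two
directed mean nearest-neighbour distances, normalising by boundary-point
counts. Both-empty region pairs score 1.0 for Dice/IoU with a warning;
contour metrics raise a named error for an empty side, and set-level
aggregation skips and counts such pairs. Probability maps are binarized
at 0.5 (configurable) before scoring.

## Phantom generator

Model: `image = clip(bias × (background + lesion) × (1 + σ·n), 0, 1)`.

- Background level 0.5; lesions are hypoechoic (darker) by `contrast`
  (default 0.15).
- Lesion geometry: rotated ellipse sized from `lesion_area_fraction`
  (default 0.1 of the image) with 3–5 random radial Fourier harmonics
  (amplitudes 0.02–0.08) — irregular but exactly rasterised contours, so
  ground truth is exact by construction. Lesions keep a 2-px border
  margin; draws too large to fit are scaled down rather than rejected.
- Speckle: multiplicative Gaussian `(1 + σ·N(0,1))`, σ default 0.3 — the
  standard first-order surrogate for fully developed speckle.
- Nonuniformity: a broad Gaussian bump normalised to mean 1, amplitude
  default 0.2.

Defaults put per-pixel class separation well below the speckle standard
deviation (gap 0.15 vs noise std ≈ 0.15 inside the lesion), so plain
thresholding fails while a small trained network succeeds — the regime
the method is designed for. Statistical contracts (mean lesion/background
gap within 20% of `contrast` over ≥100 seeds; noise std monotone in σ;
no lesion pixel on the border) are asserted in the test suite.

What the phantoms do **not** model: point-spread-function blur and the
spatial correlation of real speckle, acoustic shadowing and enhancement,
posterior echo patterns, heterogeneous tissue texture, and operator
variability in ROI placement. Passing the end-to-end tests therefore
demonstrates that the implementation is correct and the training dynamics
behave as designed — not that any particular clinical accuracy would be
reached on scanner data.

## Problem sizes and reproducibility

The desk-scale study configuration used by the test suite and the
acceptance script: 200 training + 50 validation 64×64 phantoms at default
noise settings, depth-3/base-8 network, 10 epochs of batch-8 Adam at the
default hyperparameters — chosen so a full training run completes in a
few minutes on a single CPU core. Under that budget the composite loss
reaches ≥0.85 held-out Dice and at least matches BCE-only and Dice-only
training at identical seeds and budgets.

All randomness (phantom sampling, weight init, batch shuffling) flows
from explicit integer seeds through `numpy` generators; identical
config + seed reproduces images and training trajectories bit-identically
on a given platform. Checkpoints embed the architecture config.

## Known limitations

- Training is CPU-bound numpy; fine at desk scale, not sized for clinical
  resolution (e.g. 512×512) datasets.
- Batch-norm statistics make the *training* trajectory depend on batch
  composition; inference uses running statistics and is batch-independent.
- The spatial-attention gate uses one convolution over two pooled maps;
  gates are bounded in (0,1) but nothing forces them to be informative on
  untrained weights.
- `hist_equalize` quantizes to J levels before mapping; pathological
  inputs concentrated in one bin map to a constant 1.0 image by design.
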