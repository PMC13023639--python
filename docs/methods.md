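# Methods

## Problem and scope

Intravascular optical coherence tomography (OCT) produces grayscale
cross-sections of vessels in which the blood-filled lumen appears as a
small dark disk (typically under 3% of the frame) inside a bright,
concentric wall. Segmenting the lumen contour precisely — Dice for
volumetric overlap, HD95 for boundary error at the ~5 µm native pixel
spacing — is the task this toolkit addresses. Clinical OCT datasets are
private, so the package ships a synthetic phantom generator that
reproduces the modality's stated structural priors and makes the entire
pipeline trainable and testable end to end.

## Differentiable substrate

No deep-learning framework is assumed. The package contains a compact
reverse-mode automatic-differentiation engine over numpy arrays
(`octseg.grad`): a `Tensor` graph with broadcasting-aware elementwise
ops, batched matmul, 2-D convolution (tap-accumulation form), circular
depthwise convolution, bilinear grid sampling differentiable in both the
source and the sampling coordinates, max-pool morphology, softmax,
LayerNorm, and an AdamW optimizer. Every primitive is validated against
central finite differences in float64; the default compute dtype is
float32. This keeps the toolkit self-contained and makes every numerical
kernel — notably the deformable convolution — a from-scratch, inspectable
implementation.

## Phantom model

A frame is a radial intensity profile plus multiplicative speckle:

- **Geometry.** Lumen disk of radius R at a (jittered) center; intensity
  profile is a lumen plateau, a linear ramp to the wall peak at
  R + w/2 (w the wall thickness), then an exponential decay toward the
  background with decay length w/2. This reproduces a dark lumen inside
  a bright concentric annulus; no claim of wave-optics realism is made.
- **Speckle.** OCT speckle amplitude follows a Rayleigh distribution and
  acts multiplicatively. The multiplier is `M = 1 + s·(R − 1)` with
  `R ~ Rayleigh(σ₀)`, `σ₀ = √(2/π)` so `E[R] = 1`. At the default
  strength s = 1 this is the pure unit-mean Rayleigh multiplier; s → 0
  is the noise-free limit, and `E[M] = 1` at every strength so expected
  brightness is speckle-invariant.
- **Defaults.** 512×512 frames; per-frame draws keep the lumen fraction
  between ~1.1% and ~2.8% of the frame (inside the modality's <3%
  envelope), wall thickness 4–8% of the frame, speckle strength 0.8–1.0.
  An optional guidewire-shadow sector is off by default.
- **Augmentations** (training-time, seeded): Gaussian noise σ = 0.05 of
  the intensity range, rotation ±15°, horizontal/vertical flips, scaling
  [0.9, 1.1], translation ±10%, elastic deformation (α = 50, σ = 5 —
  calibrated to the native 512 px frame), brightness/contrast jitter.
  Each transform fires independently with probability 0.5; geometric
  transforms are applied identically to image and mask (nearest-neighbor
  for the mask, re-binarized), photometric ones to the image only.

What the phantom does **not** emulate: catheter/NURD artifacts,
trilaminar wall-layer texture, log-compression statistics of raw
interferograms, spatially correlated speckle. Passing the scaled-down
training study therefore shows the architecture and losses can learn
annular dark-lumen segmentation under Rayleigh speckle — not clinical
performance.

## Network

A four-stage pyramid-transformer encoder (strides 4/8/16/32) with
spatial-reduction attention (SRA: keys/values pooled by a strided
convolution per stage) and a strictly single-channel stem (OCT is
grayscale; a duplicated-RGB stem triples stem weights for no
information). Three specialized decoder modules, each with an ablation
flag:

- **Radial Intensity Module (RIM)** on the stage-1 features: a
  differentiable Cartesian→polar resample (normalized radius
  `r = 2·√((x−cₓ)²+(y−c_y)²)/(D−1)`, angle `θ = atan2/π ∈ (−1,1]`,
  default 720 bins = 0.5°), a circular depthwise convolution along θ
  (length 7, delta-initialized), a DCT-II channel attention (first 16
  orthonormal coefficients of the radially-averaged angular profile →
  bottleneck MLP → sigmoid gate), inverse polar→Cartesian resampling
  with circular θ interpolation, and a residual add. The polar center
  defaults to the image center (catheter-centered prior); a
  dark-centroid estimator (intensity-weighted centroid of the darkest
  decile) is available.
- **Deformable cross-scale fusion (D-CFM)**: a zero-initialized 3×3
  convolution over `Concat(Up(f_m), f_l)` predicts 2·9 per-pixel tap
  offsets; the deformable convolution gathers `f_l` at
  `p + p_k + Δp(p, p_k)` by border-replicated bilinear interpolation
  (differentiable in input, offsets and kernel); a Sobel-magnitude gate
  `σ(Conv₁ₓ₁(|∇f̄_l|))` multiplies the deformable output, and the fusion
  is the residual form `g ⊙ f_def + Proj(Up(f_m))`. Stage 4 is fused
  into stage 3, then into stage 2 by default.
- **Boundary-aware attention (BAM)** on the combined map: a
  Laplacian-of-Gaussian edge indicator (σ = 1 px; threshold = the 90th
  percentile of the absolute response by default, a fixed threshold
  optionally) modulates the attention queries — `Q = W_q(E ⊙ f)`,
  `K, V` from `f` — inside non-overlapping 7×7 windows
  (replicate-padded, exactly un-padded). The binary edge map is a
  constant under backpropagation. The output projection is
  zero-initialized so the block starts as the identity.

Two 1×1 heads produce logits: the main head after BAM, an auxiliary head
on the fused mid-level map (deep supervision, weight 0.5). Both biases
are initialized at the foreground prior, `logit(0.02) ≈ −3.9`: an
uninformed 0.5 start over-predicts a <3% foreground ~25-fold, and the
resulting early correction can drive logits into sigmoid saturation — a
dead state float32 cannot leave.

## Losses and metrics

Training objective:
`L_total = 0.5·L_Dice + 0.3·L_BIoU + 0.2·L_FT`.

- Soft Dice: `1 − 2Σpg/(Σp + Σg + ε)`, ε = 1e-6.
- BoundaryIoU on 2-px-dilated boundary bands. The hard band of a binary
  mask is `(m XOR erode(m))` dilated twice with the 3×3 square
  (Chebyshev radius 2). The soft (training) band is the same formula on
  probabilities via max-pool morphology — `dilate²(p − erode(p))`,
  erosion as `−maxpool(−p)` with zero background — and converges to the
  hard band as the map binarizes. Both bands empty is defined as a
  perfect 0.
- Focal Tversky: `TI = TP/(TP + 0.3·FP + 0.7·FN)` on soft counts,
  loss `(1 − TI)^{4/3}` — the β = 0.7 asymmetry penalizes missed lumen
  pixels, the focal exponent emphasizes hard cases.

Evaluation: Dice/IoU from the confusion counts (both-empty = 1.0 by
convention), and HD95 as the 95th linear-interpolated percentile of the
pooled symmetric boundary-to-nearest-boundary distances (KD-tree
queries), reported in pixels and in millimetres at the default 0.005
mm/px spacing. HD95 with an empty mask is reported as missing, never
as zero.

## Training procedure

AdamW (default lr 1e-4, the full-scale recipe) at constant learning
rate, optional linear warmup, global gradient-norm clipping at 1.0,
early stopping on validation Dice (patience 10), best-by-validation-Dice
checkpointing. One integer seed drives weight init, batch order and
augmentation draws; two runs with the same seed are bit-identical.

### Scaled-down study sizes

Full-scale training (512 px, GPU) is out of scope, so the repeatable
experiment is: 100 phantoms at 64×64 (80/20 split by phantom identity),
the `TINY_CONFIG` backbone (widths 12/24/32/40, depth 1 per stage,
decoder width 16, 120 angular bins), 15 epochs, AdamW lr 2e-3 with
50-step warmup, batch 8, weight decay 0, repeated over 5 derived seeds;
a companion 10-seed, 5-epoch run on 32 phantoms checks that the training
loss decreases from epoch 1 to epoch 5. The tiny model trains from
scratch in ~150 steps, which is why its learning rate is 20× the
full-scale default; the warmup and prior-bias initialization exist
because overlap-only losses on a <3% foreground otherwise occasionally
drive the heads into saturated all-background or all-foreground states
from which float32 gradients cannot recover.

## Numerical choices and degenerate inputs

- ε = 1e-6 in all ratio losses; sigmoid exponent clamped at ±60
  (bit-identical in float32, avoids overflow warnings).
- Bilinear sampling clamps coordinates to the border (replicate
  semantics); the coordinate gradient is zeroed where the clamp
  saturates.
- Polar inverse resampling wraps θ circularly (the seam at θ = ±1
  interpolates across the first/last bins); pixels outside the inscribed
  disk fall back to zeros (or a caller-supplied map).
- Max-pool morphology breaks gradient ties by first-claimed position.
- Constant feature maps give empty LoG edge maps (strict inequality at
  the threshold) and uniform attention — well-defined, finite outputs.
- Inputs not divisible by 32 are reflect-padded and cropped back.

## Known limitations

- The backbone is trained from scratch; no pretrained weights, so
  parameter counts and accuracy are not comparable to published
  full-scale systems.
- The phantom's realism gap (above) bounds what the end-to-end study can
  claim about clinical frames.
- Single-image 2-D processing only; no use of pullback continuity.
- The attention uses single-head, non-shifted windows by default;
  relative position biases and cross-window mixing are out of scope.
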