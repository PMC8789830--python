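# Methods

## Problem

OCT angiography (OCTA) contrasts blood flow against static tissue by
comparing repeated B-scans taken at the same slow-axis location:
moving red blood cells decorrelate the backscattered signal between
repeats, static tissue does not.  Image quality therefore scales with
the number of repeats (it saturates near eight), and lateral
resolution scales with the raster-scan step density — both directly
multiply acquisition time.  `octarec` reconstructs a fully-sampled,
8-repeat-quality enface angiogram from an acquisition that undersamples
the enface plane by a ratio r on each axis and uses only two repeats,
which is r² · (8/2) times faster to acquire.

## Reconstruction model

The generator runs two convolutional modules in series:

* **Super-resolution (SR) module.**  A 9×9 convolution extracts
  low-level features; a *Deep layer* of 3×3 convolution blocks with
  PReLU activations (trainable per-channel leakage) extracts
  high-frequency residuals; the two paths merge by element-wise
  summation; log₂ r pixel-shuffle stages (each a convolution to 4×
  channels followed by a ×2 periodic sub-pixel rearrangement) upsample
  to the full grid; a 9×9 convolution produces the output.  Pixel
  shuffle is used instead of transposed convolution to avoid
  checkerboard artifacts.
* **Quality-enhancement (QE) module.**  The same pipeline without the
  upsampling stages: it preserves the feature-map size and compensates
  for the repeat count (two repeats in, eight-repeat quality out).

Two Deep-layer wirings are available.  The *dense* connection feeds
each block the channel-concatenation of the layer input and all
previous block outputs, with a final 1×1 fusion convolution restoring
the base width (so with n blocks the fusion sees `channels·(n+1)`
inputs).  The *residual* connection adds each block's output to its
input.  Defaults: 5 blocks, 64 base channels — reduced in the
desk-scale experiments below.

**Output activation.**  Module exits squash their logits through a
sigmoid, bounding predictions in (0, 1) to match the [0, 1] data
normalization.  A hard clip was evaluated first and rejected: enface
angiograms are dark (mean intensity ≈ 0.07 in the synthetic sets), the
mean-absolute-error term drives the entire pre-clip map below zero
within one epoch, every pixel saturates, and the gradient is then
identically zero with no restoring force — training never recovers.
The sigmoid keeps a (small) gradient everywhere, and the output conv
is initialized at 0.1× He scale so first predictions sit near
mid-range.

The adversarial discriminator is a strided 3×3 convolution stack
(channels doubling per stride-2 stage from the base width up to 8×,
batch-normalized, leaky-ReLU 0.2), global average pooling and a
sigmoid.  Its probability is clamped to [1e-7, 1−1e-7] so the log
losses stay finite when the sigmoid saturates in floating point.  The
exact stack depth/width of the original design is not public; this
SRGAN-family sizing is the package's documented assumption.

## Losses

For ground truth Y and reconstruction Ŷ (each N pixels, values in
[0, 1]):

* MAE = (1/N) Σ |Y − Ŷ| — the primary term;
* MS-SSIM loss = 1 − MSSSIM(Y, Ŷ) — multiscale structural similarity
  with an 11×11 Gaussian window (σ = 1.5), standard per-scale
  exponents (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), contrast–
  structure terms at every scale and luminance at the coarsest, 2×2
  average pooling between scales;
* FMAE = (1/N) Σ ||F(Y)| − |F(Ŷ)|| — mean absolute difference of the
  unnormalized 2-D DFT magnitudes (one division by N, matching the
  definition literally; no logarithmic compression of the magnitudes).

Combined: `L = MAE + 0.8·MS-SSIM-loss + 7e-5·FMAE`.  Adversarial
training adds `5e-3·(−log D(G(X)))` for the generator and minimizes
`−[log D(Y) + log(1 − D(G(X)))]` for the discriminator (stability
epsilon 1e-8 inside the logarithms).

Numerical choices: with fewer than five scales the MS-SSIM exponents
are renormalized to sum to one over the scales used; mean
contrast-structure and luminance terms are clamped at 1e-6 before the
fractional exponent (negative values have no real fractional power);
images too small for the requested scale count raise an error naming
the feasible maximum (size must stay ≥ the window through the dyadic
reductions).  All losses are differentiable; the analytic gradients
are verified against central differences to 1e-4 on 8×8 instances.

## Training schedule

Per mini-batch, three updates in order: (1) the SR module against the
(HR, LQ) intermediate target, (2) the QE module against (HR, HQ),
consuming the SR output with gradients detached so the stages stay
isolated, (3) the concatenated end-to-end network against (HR, HQ) at
`learning_rate × finetune_lr_factor` (default 0.1).  He-normal
initialization, Adam, L2 penalty (default 1e-5), early stopping on the
validation combined loss with patience 10 and a minimum improvement of
1e-4 (so float-level noise does not reset patience); the
best-validation weights are restored at the end.  The adversarial
stage alternates discriminator/generator updates per batch and
monitors the same non-adversarial validation loss for stopping.
Hyper-parameter defaults (LR 1e-4, batch 8) follow common
super-resolution practice and are exposed in `TrainConfig`.

The engine is a compact numpy reverse-mode autodiff implementation
(`octarec._autograd`).  Stride-1 convolutions with kernels ≥ 5×5
evaluate via real-FFT products (mathematically identical; gradients
follow from the correlation theorem and are gradient-checked), which
makes the 9×9 convolutions affordable on a CPU.  Training runs in
float32; everything else defaults to float64.

## Synthetic phantoms

The phantom generator emulates the statistical structure of repeated
B-scan volumes, not anatomy:

* **Geometry** — vessels are correlated-random-walk centerlines
  (persistence 0.85) dilated to tubes with per-vessel radii drawn from
  `radius_range` (default 1.5–3 voxels); connected curvilinear
  structures are what the skeleton-based connectivity metric needs.
* **Background** — smoothed, clipped Gaussian speckle
  (mean ≈ 0.30, σ ≈ 0.08), giving a nonzero static decorrelation floor
  like real speckle.
* **Flow** — vessel voxels carry a bright baseline (0.55) plus an
  AR(1) process with stationary σ = 0.15 and one-repeat correlation
  `1 − flow_decorrelation` (default 0.7); static voxels vary only by
  additive Gaussian noise (`static_noise_sigma`, default 0.02).  Both
  defaults are set so that, as in real data, a 2-repeat angiogram is
  visibly noisier than an 8-repeat one while vessels remain the
  dominant signal.

The decorrelation angiogram is the mean absolute difference over
adjacent repeat pairs, min-max normalized per volume (an all-constant
volume maps to zeros).  The exact estimator used for the in-vivo data
this design targets is not public; this first-order estimator
reproduces the property the pipeline relies on — estimator dispersion
shrinks with repeat count — which the tests assert over 50 seeded
phantoms.  Enface undersampling is strided subsampling (every r-th
sample), mimicking a coarser raster scan that skips positions rather
than averaging them; consequently interpolation baselines use the
corner-aligned sample-grid convention (LR pixel (i,j) ↔ HR (r·i, r·j)),
which makes downsample∘upsample an exact round trip.

What passing these tests does **not** show: phantoms are aligned by
construction (no bulk motion or registration errors), speckle is
Gaussian rather than Rayleigh-like, vessel trees have no branching
hierarchy or depth-dependent signal decay, and absolute metric values
on in-vivo angiograms will differ.  The synthetic results support
ordering statements (trained reconstruction > interpolation; more
repeats > fewer), not absolute performance claims.

## Desk-scale experiment sizes

The end-to-end ordering study (`octarec.experiments`) uses 200
training + 30 held-out pairs of 48×48 enface slices at ratio 2 from
seeded phantoms, a 12-channel 2-block generator, 2 MS-SSIM scales
(48 px supports at most two 11-px windows across the dyadic
reduction), learning rate 1e-3, 15 epochs.  These sizes are the
package's choice of a single-CPU-scale experiment; the trained
generator exceeds bicubic interpolation's held-out SSIM by ≈ 0.14
under them, and dense and residual variants land within ≈ 0.01 of each
other.  Larger nets/pairs only widen the margin.

## Other numerical conventions

* Axis order (R, X, Y, Z), x/y the enface plane, z depth, 0-based;
  volumes stored as uint16 multi-page TIFF with linear [0,1] scaling
  (round trips exact to 1/65535) and JSON metadata.
* Rotation/flip augmentation uses the 8-element symmetry group of the
  square only — interpolation-free, so ground truth stays exact; one
  element transforms all three images of a paired sample.
* "Two sequential repeats chosen at random" = a uniformly drawn
  adjacent index pair (i, i+1).
* The 9:1 split takes `round(0.9·n)` training samples; 2000 → 1800/200.
* PSNR uses data range 1; identical images are flagged infinite and
  excluded from report means with a warning.  Vessel connectivity
  binarizes with Otsu by default (constant images have no foreground),
  skeletonizes, labels 8-connected components, and reports the
  fraction of skeleton pixels in components of ≥ 5 pixels; an empty
  foreground yields NaN with a warning.
* The acquisition model multiplies r² (both enface axes) by 8/n
  (repeats); times are reported at two significant figures but never
  coarser than 0.1 s.
* The bilateral filter is a windowed implementation normalized over
  the in-bounds window (truncated at 3 spatial sigmas), so outputs are
  convex combinations of input pixels; default sigmas (3 px spatial,
  0.1 range) are documented assumptions.
* Networks can be applied to sectioned slices or directly to MIP
  enface images; direct application is the default evaluation path.

## Known limitations

Training on a CPU limits practical problem sizes; the adversarial
stage is exercised at toy scale in the tests.  The phantom's
simplifications above mean quantitative in-vivo performance must be
established on real paired acquisitions via the `pair`/`train`/
`evaluate` commands.
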