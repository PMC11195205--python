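# Methods

This note documents the models, parameter choices and numerical conventions
behind `scopesr`, and what its synthetic-data experiments do and do not show.

## Canonical image representation

Images are float32 arrays normalized to [0, 1] by the maximum representable
value of their storage dtype (uint8 or uint16), with explicit axis-role
labels from `TZCYX` and `Y`, `X` always last. The [0, 1] convention makes
crappifier intensity parameters comparable across bit depths; the original
dtype is retained so writes quantize back to the native range (round-trip
error ≤ one quantization step). TIFF files with absent or nonstandard axis
metadata get leading axes labelled `T` then `Z` — a fixed convention chosen
so dimension configs stay portable. Coordinates are 0-based and tile boxes
are half-open intervals.

## Degradation model

Degradation is strictly **downsample, then add noise**. Downsampling is area
(box) averaging over `scale × scale` blocks, which models detector binning
and makes the order argument exact: averaging k = scale² independent noise
values divides their variance by k, so the reverse order (noise first)
produces inputs whose noise variance is ≈ scale² too small. A bilinear
downsampling kernel is available for comparison with interpolation-based
pipelines but is not the default.

Noise families, on normalized intensities x ∈ [0, 1]:

- **poisson**: `x → Poisson(x·gain/max(i, ε)) · max(i, ε)/gain`, where `gain`
  is the expected photon count of a full-scale pixel at intensity i = 1 and ε
  = 1e-6 guards the i → 0 limit. Larger intensity means fewer effective
  photons. The pre-clipping mean equals x; the variance at intensity 1 is
  x/gain. Default gain 200 corresponds to a few hundred photons per
  full-scale pixel, a realistic regime for fast confocal scans.
- **additive_gaussian**: `x + N(0, i)`; i is the standard deviation in
  normalized units.
- **poisson_gaussian**: Poisson stage then Gaussian stage (the standard mixed
  shot-plus-read-noise model).

Outputs are clipped to [0, 1] by default (disable `clip` for noise-statistics
work). Noise intensity is drawn once per `crappify` call — i.e. per training
item, per epoch — from a uniform range; this is the finest natural
granularity for intensity augmentation and means every epoch degrades every
tile differently, multiplying the effective diversity of the training set.

## Noise-model calibration

Given real (HR, LR) pairs, the noise profile is `LR_true − downsample(HR)`,
unclipped. Candidate crappifier parameters are scored by the mean (over
pairs) 1-Wasserstein distance between the value distributions of the true
profile and a synthetic profile generated at those parameters. Wasserstein-1
was chosen because it is robust to shifted/scaled noise laws and has an
exact sorted-sample estimator; residual arrays are subsampled to ≤ 10⁵
values per evaluation, well past the point where the estimate stabilizes.

Minimization is Bayesian optimization with a Gaussian-process surrogate:
Matérn-5/2 kernel with a small White-noise term, inputs rescaled to the unit
box, expected-improvement acquisition maximized over 512 fresh uniform
candidates per iteration, after a 10-point uniform random initial design
(`n_calls` total evaluations, default 40). A single shared noise seed is used
for every candidate evaluation so the objective surface is
quasi-deterministic, which the GP model assumes. Acquisition by random
candidate search (rather than gradient multistart) keeps the loop simple and
fully seeded; with 1–2 parameters on a box it is not a limitation.

Measured behaviour (recomputed by `scripts/acceptance.py`): for additive
Gaussian noise at σ ∈ {0.05, 0.1, 0.2} on 4 synthetic pairs of 256×256, the
fitted σ's median relative error is well inside 15%.

## Tiling and splitting

Tiles are square, laid on a regular grid of stride `tile_size − overlap`.
Boundary handling is `drop` for training (partial tiles would need padding
that contaminates targets) and `pad_reflect` for prediction (full coverage).
Non-spatial axes are flattened into frames; a dataset item is one (tile
position, frame). Train/validation splitting shuffles distinct (image,
tile-position) keys and assigns whole tiles, because frames of one tile are
near-duplicates and must not straddle the split. Stitching averages
overlapping regions with equal weights — the simplest scheme with an exact
round-trip property (`stitch(tile(x)) == x` to float tolerance on non-padded
regions). Asymmetric input/output dimensionality is expressed by an odd
`in_frame_window`: the input is a window of adjacent frames (reflected at
stack ends) centered on the single target frame.

## Model and training

The restoration network is a residual U-Net: a stem convolution,
`depth` encoder levels (residual block + stride-2 convolution, widths
doubling from `base_channels`), a bottleneck residual block, and mirrored
decoder levels (pixel-shuffle upsampling, skip concatenation, fuse
convolution, residual block), finished by a pixel-shuffle head when
scale > 1. The network predicts a residual against the nearest-neighbour
upsampled input, so the identity mapping is available from step one — this
markedly accelerates convergence at desk scale. Residual-block details (two
3×3 convolutions, post-add ReLU) and He-normal seeded initialization follow
common super-resolution practice. Input spatial extents must be divisible by
2^depth.

The tensor core (`scopesr.nn`) is a compact reverse-mode automatic
differentiation engine over numpy, implementing exactly the operations the
models and the loss require (convolution via im2col + GEMM, pixel shuffle,
pooling, separable blurring, broadcast arithmetic). Training uses Adam
(default learning rate 5e-4, no schedule) on the mixed objective

    loss = α · (1 − MS-SSIM(pred, target)) + (1 − α) · mean|pred − target|

with α = 0.84 following the mixed-loss literature; the Gaussian-weighted L1
of that literature is simplified to plain L1. Runs are fully seeded and
reproducible on one device; the best-validation checkpoint is retained.

## Metrics

- **PSNR**: `10·log₁₀(range²/MSE)`, capped at 100 dB when MSE = 0 so
  aggregates stay finite.
- **SSIM**: Gaussian-weighted (σ = 1.5, 11-pixel support), population
  statistics, constants C1 = (0.01 L)², C2 = (0.03 L)², reflect-boundary
  filtering, half-window border cropped — matching the standard reference
  definition (verified against scikit-image to ~1e-9 in the tests).
- **MS-SSIM**: valid-mode Gaussian windows (11 taps, σ = 1.5), 2×2
  average-pool between levels with odd extents cropped by one pixel,
  contrast-structure terms clamped at zero, standard five-level weights
  truncated to the level count and renormalized (default 3 levels, suitable
  for 64–256 px tiles). The same code path, made differentiable by the
  autograd core, serves as the training loss; the test suite checks it
  against an independent direct implementation.

Benchmarking restores each true-LR image by tiled inference and scores it
against HR with all three metrics, next to a bilinear upscaling of the same
input — the no-learning control. Control columns are a pure function of the
data.

## Synthetic study conditions

The generator renders Gaussian puncta (analytic blobs, amplitude-uniform in
0.4–0.9 of headroom, minimum separation 4σ_PSF + 2 px so peaks stay
resolvable) and random-walk filaments blurred by a Gaussian PSF (σ = 2 px)
on a 0.1 background; defaults are 256×256 with 40 spots and 3 filaments.
These mimic the sparse bright structures and smooth optics of fluorescence
micrographs at desk scale, with no claim of optical realism: no spatially
correlated noise, scan artifacts, drift, or realistic PSF anisotropy.
Passing results on this data demonstrate that the pipeline's mechanics and
statistics are correct, not field performance on any particular instrument.

The standard experiment trains a scale-2, base-16, depth-3 residual U-Net
for ≈ 500 steps (72 epochs × 7 batches) on ≈ 50 crappified 64×64 tiles from
4 specimens (Poisson crappifier, gain 200, intensity ∈ [0.5, 1.5]) and
benchmarks on 10 held-out pairs degraded at fixed intensity 1.0. At these
sizes the run takes a couple of minutes on one CPU core and the trained
model beats the bilinear control by ≈ 2–3 dB PSNR and ≈ 0.1 SSIM.

## Numerical conventions and edge cases

- All computation in float32 (metrics accumulate in float64).
- Every random draw flows from an explicit integer seed; child seeds are
  derived via `numpy.random.SeedSequence` and kept below 2³¹.
- `downsample` raises on non-divisible extents unless `crop=True`.
- `apply_noise` with family `none` is exactly the identity; intensity 0 with
  additive Gaussian likewise.
- PSNR of identical images returns the documented 100 dB cap.
- Training aborts with a diagnostic on non-finite loss.
- The training loss auto-caps the MS-SSIM level count to what the tile size
  supports (the public `ms_ssim` instead raises and advises fewer levels).

## Known limitations

- Single-device, single-precision training only; no schedules, mixed
  precision, or adversarial/perceptual losses.
- The numpy compute core is CPU-bound; it is sized for small models and
  tiles, not production-scale training.
- No spatially varying noise fields, PSF/blur fitting, or registration of
  misaligned pairs.
- `predict_image` restores one frame at a time (multi-frame-window models
  are trained through the dataset API but whole-image inference assumes
  single-frame input).
- Proprietary microscope formats (CZI, ND2, LIF) and RGB images are out of
  scope; use single- or multi-page grayscale TIFF.
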