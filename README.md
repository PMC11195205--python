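# scopesr

Super-resolution and denoising of point-scanning microscopy images via
semi-synthetic training pairs.

## The problem

Point-scanning microscopes (confocal, scanning EM) acquire one pixel at a
time, so resolution, signal-to-noise ratio, imaging speed and sample
preservation trade off directly against each other. Deep-learning restoration
can recover high-quality images from fast, undersampled acquisitions — but
training a restoration model normally requires perfectly aligned pairs of
low- and high-quality images, which are difficult to acquire.

`scopesr` sidesteps that requirement with a **crappifier**: a parametric
degradation model that turns high-resolution ground truth into realistic
low-resolution, noisy counterparts, so aligned training pairs are
manufactured on the fly from high-quality data alone. The package covers the
full workflow:

- **Crappification** (`scopesr.crappify`) — area downsampling by an integer
  factor *s*, **then** noise injection (Poisson, additive Gaussian, or
  Poisson–Gaussian). The order matters: injecting noise before downsampling
  averages adjacent noise values together and shrinks the noise variance by
  ≈ *s*², producing training inputs far cleaner than real acquisitions. With
  noise applied after downsampling, Poisson noise — the statistically natural
  model for a photon-counting point scanner — matches real data. Noise
  intensity is redrawn per training item from a configurable range, so every
  epoch sees fresh degradations of every tile.
- **Noise-model calibration** (`scopesr.noise_fit`) — when real HR/LR pairs
  exist, the HR image is downsampled to a "noiseless" LR image and subtracted
  from the true LR acquisition, yielding a *noise profile*. Crappifier
  parameters are fitted by Gaussian-process Bayesian optimization (Matérn-5/2
  kernel, expected-improvement acquisition) minimizing the 1-Wasserstein
  distance between synthetic and true noise-profile value distributions.
- **Leakage-safe tiled datasets** (`scopesr.tiling_datasets`) — large images
  are cut into square tiles; non-spatial axes (time, depth, channel) become
  *frames* of a tile. Train/validation splitting assigns whole tiles, never
  frames, because frames of one tile are near-duplicates and splitting them
  leaks training data into validation.
- **Models** (`scopesr.models`) — a residual U-Net with pixel-shuffle
  upsampling, configurable scale (1 = pure denoising, 2/4/8 =
  super-resolution), built on a small numpy automatic-differentiation core
  (`scopesr.nn`) so the package runs anywhere numpy does.
- **Training and benchmarking** (`scopesr.train_predict`) — MS-SSIM + L1
  mixed loss, `loss = α(1 − MS-SSIM) + (1 − α)·L1` with α = 0.84; tiled
  whole-image prediction with reflect padding and overlap averaging; per-image
  PSNR / SSIM / MS-SSIM benchmarking against a bilinear-upscaling control.
- **Synthetic specimens** (`scopesr.synthetic`) — deterministic
  puncta-and-filament micrograph stand-ins with recorded degradation
  parameters, so the whole train → predict → benchmark loop runs with no
  external data.

## Worked example

```python
import numpy as np
from scopesr import *

# 1. synthetic high-resolution "acquisitions" + degradation model
crappifier = Crappifier("poisson", intensity=1.0, gain=200)
hr = {f"im{i}": generate_specimen(SpecimenSpec(shape=(256, 256), seed=i))
      for i in range(4)}

# 2. leakage-safe tiled dataset with runtime crappification (scale 2)
full = TiledDataset(hr, SlideConfig(tile_size=64), "train_crappified",
                    scale=2, crappifier=crappifier,
                    intensity_range=IntensityRange(0.5, 1.5))
tr, va = split_by_tile(full.indices, val_fraction=0.2, rng_seed=0)

# 3. train a small residual U-Net with MS-SSIM + L1 loss
model = build_resunet(ModelSpec(scale=2, base_channels=16, depth=3), seed=0)
model, history = train_model(model, full.subset(tr), full.subset(va),
                             TrainConfig(epochs=72, batch_size=8,
                                         learning_rate=1e-3, seed=0))

# 4. benchmark on held-out pairs against the bilinear control
generate_pair_set(10, SpecimenSpec(shape=(256, 256), seed=99), 2,
                  crappifier, seed=5, out_dir="bench_set")
ds = TiledDataset(load_image_dir("bench_set/hr"), None, "benchmark_paired",
                  lr_sources=load_image_dir("bench_set/lr"))
result = benchmark(model, ds)
print(f"PSNR  model {result.mean('psnr_model'):.2f} dB"
      f"  vs control {result.mean('psnr_control'):.2f} dB")
print(f"SSIM  model {result.mean('ssim_model'):.4f}"
      f"  vs control {result.mean('ssim_control'):.4f}")
```

Output from this exact run:

```
PSNR  model 37.91 dB  vs control 35.34 dB
SSIM  model 0.9818  vs control 0.8760
```

The trained model restores the noisy, half-resolution inputs ~2.6 dB more
accurately than bilinear interpolation, and the larger SSIM gap (+0.11)
reflects the denoising that interpolation cannot do.

The same workflow is available from the shell:

```sh
scopesr gen-synth --out-dir data --n-images 10 --scale 2 --seed 1
scopesr train --hr-dir data/hr --out-dir run --config train.yaml --seed 1
scopesr benchmark --checkpoint run/checkpoints/last.npz \
    --hr-dir data/hr --lr-dir data/lr --out-dir bench
scopesr predict --checkpoint run/checkpoints/last.npz \
    --lr-dir data/lr --out-dir restored
scopesr fit-crappifier --hr-dir data/hr --lr-dir data/lr --out-dir fit \
    --family additive_gaussian --bound intensity=0:0.5 --n-calls 40
```

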