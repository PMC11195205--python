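"""Semi-synthetic degradation of high-resolution images ("crappification").

A high-resolution micrograph is degraded into a realistic low-resolution,
noisy counterpart in two strictly ordered steps: area (box) downsampling
first, then noise injection. Applying the noise *after* downsampling matters:
if noise is added first, adjacent noise values are averaged away by the
downsampling kernel, shrinking the noise variance by roughly ``scale**2`` and
producing training inputs that are cleaner than real acquisitions —
particularly for value-dependent (Poisson) noise.

Noise families
--------------
``poisson``
    Photon shot noise. Each normalized pixel value ``x`` is mapped to an
    expected photon count ``x * gain / max(intensity, eps)``, a Poisson draw
    is taken, and the count is mapped back. Larger ``intensity`` means fewer
    effective photons, hence coarser statistics; the pre-clipping mean is
    preserved.
``additive_gaussian``
    Signal-independent read noise: ``x + Normal(0, intensity)``.
``poisson_gaussian``
    Poisson stage followed by a Gaussian stage (the standard mixed model for
    point-scanning detectors).
``none``
    Identity; useful for noise-free controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import ImageStack

__all__ = [
    "Crappifier",
    "IntensityRange",
    "downsample",
    "apply_noise",
    "crappify",
    "NOISE_FAMILIES",
]

NOISE_FAMILIES = ("poisson", "additive_gaussian", "poisson_gaussian", "none")

_EPS = 1e-6


@dataclass
class Crappifier:
    """Parametric degradation model applied after downsampling.

    Parameters
    ----------
    family:
        One of ``poisson``, ``additive_gaussian``, ``poisson_gaussian``,
        ``none``.
    intensity:
        Nonnegative noise strength. For Gaussian families this is the
        standard deviation in normalized units; for Poisson families it
        scales down the effective photon count.
    gain:
        Expected photon count of a full-scale pixel at intensity 1
        (Poisson families only). Must be positive.
    clip:
        Clip the output back to [0, 1] (default). Disable to study raw
        noise statistics.
    """

    family: str = "poisson"
    intensity: float = 1.0
    gain: float = 1000.0
    clip: bool = True

    def __post_init__(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; choose from {NOISE_FAMILIES}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be nonnegative, got {self.intensity}")
        if self.family in ("poisson", "poisson_gaussian") and not self.gain > 0:
            raise ValueError(f"gain must be positive for poisson families, got {self.gain}")

    def with_params(self, **params: float) -> "Crappifier":
        """Copy with updated parameters (used by the noise-model fitter)."""
        kwargs = dict(
            family=self.family, intensity=self.intensity, gain=self.gain, clip=self.clip
        )
        for key, value in params.items():
            if key not in kwargs:
                raise ValueError(f"unknown crappifier parameter {key!r}")
            kwargs[key] = value
        return Crappifier(**kwargs)


@dataclass
class IntensityRange:
    """Uniform range noise intensities are drawn from, one draw per item.

    Drawing a fresh intensity for every generated training image exposes the
    model to a spread of input qualities instead of a single fixed noise
    level. ``low == high`` degenerates to a fixed intensity.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low < 0:
            raise ValueError(f"low must be nonnegative, got {self.low}")
        if self.high < self.low:
            raise ValueError(f"high ({self.high}) must be >= low ({self.low})")

    def sample(self, rng: np.random.Generator) -> float:
        if self.high == self.low:
            return float(self.low)
        return float(rng.uniform(self.low, self.high))


def downsample(
    hr: ImageStack, scale: int, *, crop: bool = False, kernel: str = "area"
) -> ImageStack:
    """Downsample the spatial (Y, X) axes by an integer factor.

    The default ``area`` kernel averages each ``scale x scale`` block, which
    models detector binning. A ``bilinear`` kernel is available for parity
    with interpolation-based pipelines. Non-spatial axes are untouched.

    Raises a shape error when extents are not divisible by ``scale`` unless
    ``crop=True``, which trims trailing rows/columns first.
    """
    if scale < 1 or int(scale) != scale:
        raise ValueError(f"scale must be a positive integer, got {scale}")
    scale = int(scale)
    if scale == 1:
        return hr.with_data(hr.data.copy())
    h, w = hr.spatial_shape
    if h % scale or w % scale:
        if not crop:
            raise ValueError(
                f"spatial extents ({h}, {w}) not divisible by scale {scale}; "
                "pass crop=True to trim"
            )
        data = hr.data[..., : h - h % scale, : w - w % scale]
        h, w = data.shape[-2], data.shape[-1]
    else:
        data = hr.data

    if kernel == "area":
        lead = data.shape[:-2]
        out = data.reshape(*lead, h // scale, scale, w // scale, scale).mean(axis=(-3, -1))
    elif kernel == "bilinear":
        from skimage.transform import resize

        lead = data.shape[:-2]
        flat = data.reshape(-1, h, w)
        out = np.stack(
            [
                resize(f, (h // scale, w // scale), order=1, anti_aliasing=True)
                for f in flat
            ]
        ).astype(np.float32)
        out = out.reshape(*lead, h // scale, w // scale)
    else:
        raise ValueError(f"unknown kernel {kernel!r}; choose 'area' or 'bilinear'")
    return hr.with_data(out.astype(np.float32))


def _noise_arrays(
    values: np.ndarray, crappifier: Crappifier, intensity: float, rng: np.random.Generator
) -> np.ndarray:
    family = crappifier.family
    if family == "none":
        return values.copy()
    out = values.astype(np.float64)
    if family in ("poisson", "poisson_gaussian"):
        step = max(intensity, _EPS) / crappifier.gain
        rate = np.clip(out, 0.0, None) / step
        out = rng.poisson(rate).astype(np.float64) * step
    if family in ("additive_gaussian", "poisson_gaussian"):
        out = out + rng.normal(0.0, intensity, size=out.shape)
    return out.astype(np.float32)


def apply_noise(
    lr_clean: ImageStack, crappifier: Crappifier, intensity: float, rng_seed: int
) -> ImageStack:
    """Inject noise of the crappifier's family at the given intensity.

    The pre-clipping expectation equals the input for the poisson and
    additive_gaussian families. Identical (inputs, seed) give identical
    output.
    """
    if intensity < 0:
        raise ValueError(f"intensity must be nonnegative, got {intensity}")
    rng = np.random.default_rng(rng_seed)
    out = _noise_arrays(lr_clean.data, crappifier, float(intensity), rng)
    if crappifier.clip and crappifier.family != "none":
        out = np.clip(out, 0.0, 1.0)
    return lr_clean.with_data(out)


def crappify(
    hr: ImageStack,
    scale: int,
    crappifier: Crappifier,
    intensity_range: IntensityRange,
    rng_seed: int,
) -> tuple[ImageStack, float]:
    """Degrade a high-resolution image: downsample, then add noise.

    The noise intensity is drawn once from ``intensity_range`` using the
    seeded stream, so successive calls with different seeds on the same image
    yield distinct degradations. Returns the degraded image and the drawn
    intensity.
    """
    rng = np.random.default_rng(rng_seed)
    drawn = intensity_range.sample(rng)
    lr_clean = downsample(hr, scale)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    lr_noisy = apply_noise(lr_clean, crappifier, drawn, noise_seed)
    return lr_noisy, drawn
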