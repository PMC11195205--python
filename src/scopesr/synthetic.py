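"""Synthetic point-scanning-style specimens with known degradation parameters.

Generates ground-truth micrograph stand-ins — Gaussian puncta (vesicle-like
spots) and smooth random-walk filaments on a uniform background, blurred by a
Gaussian point-spread function — plus paired high/low-resolution sets whose
degradation parameters are recorded. Every other module of the package can be
exercised end to end against these images, and the recorded parameters serve
as ground truth for noise-model recovery.

No claim of optical realism is made: the generator reproduces the *texture
statistics* restoration models care about (sparse bright structures, smooth
blur, value-dependent noise), not a physical microscope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .crappify import Crappifier, downsample, apply_noise
from .image_io import ImageStack, write_image

__all__ = ["SpecimenSpec", "generate_specimen", "generate_pair_set"]


@dataclass
class SpecimenSpec:
    """Parameters of one synthetic specimen image.

    Puncta are rendered as analytic Gaussian blobs (peak height = amplitude),
    placed with a minimum separation of ``4 * psf_sigma`` so individual spots
    remain resolvable. Filaments are random-walk polylines rasterized and
    blurred with the PSF.
    """

    shape: tuple[int, int] = (256, 256)
    n_spots: int = 40
    n_filaments: int = 3
    psf_sigma: float = 2.0
    background: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 32 or self.shape[1] < 32:
            raise ValueError(f"shape must be at least 32x32, got {self.shape}")
        if not 0 <= self.background < 1:
            raise ValueError(f"background must be in [0, 1), got {self.background}")


def _place_spots(
    rng: np.random.Generator, shape: tuple[int, int], n: int, min_sep: float
) -> np.ndarray:
    """Rejection-sample spot centers with a minimum pairwise separation."""
    h, w = shape
    margin = min_sep
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n and attempts < 200 * max(n, 1):
        attempts += 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep**2 for cy, cx in centers):
            centers.append((y, x))
    return np.array(centers, dtype=np.float64).reshape(-1, 2)


def generate_specimen(spec: SpecimenSpec) -> ImageStack:
    """Render one deterministic synthetic specimen image in [0, 1]."""
    import warnings

    if spec.n_spots == 0 and spec.n_filaments == 0 and spec.background == 0:
        warnings.warn("specimen with no structures and zero background is entirely dark")

    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    canvas = np.full((h, w), spec.background, dtype=np.float64)

    # Puncta: analytic Gaussian blobs so the peak equals the drawn amplitude.
    sigma = max(spec.psf_sigma, 0.5)
    min_sep = 4.0 * sigma + 2.0
    centers = _place_spots(rng, spec.shape, spec.n_spots, min_sep)
    half = int(np.ceil(4 * sigma))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernel = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    for cy, cx in centers:
        amp = rng.uniform(0.4, 0.9) * (1.0 - spec.background)
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
        canvas[y0:y1, x0:x1] += amp * kernel[
            y0 - (iy - half) : kernel.shape[0] - ((iy + half + 1) - y1),
            x0 - (ix - half) : kernel.shape[1] - ((ix + half + 1) - x1),
        ]

    # Filaments: smooth random walks rasterized as impulses, PSF-blurred.
    if spec.n_filaments > 0:
        layer = np.zeros((h, w), dtype=np.float64)
        for _ in range(spec.n_filaments):
            y = rng.uniform(0.1 * h, 0.9 * h)
            x = rng.uniform(0.1 * w, 0.9 * w)
            angle = rng.uniform(0, 2 * np.pi)
            n_steps = int(0.8 * max(h, w))
            for _ in range(n_steps):
                angle += rng.normal(0.0, 0.15)
                y = float(np.clip(y + np.sin(angle), 1, h - 2))
                x = float(np.clip(x + np.cos(angle), 1, w - 2))
                layer[int(y), int(x)] += 1.0
        layer = gaussian_filter(layer, sigma)
        peak = layer.max()
        if peak > 0:
            layer *= rng.uniform(0.4, 0.8) * (1.0 - spec.background) / peak
        canvas += layer

    return ImageStack(np.clip(canvas, 0.0, 1.0).astype(np.float32), "YX")


def generate_pair_set(
    n: int,
    spec: SpecimenSpec,
    scale: int,
    crappifier: Crappifier,
    seed: int,
    out_dir: str | Path,
    *,
    overwrite: bool = False,
) -> dict:
    """Write ``n`` filename-matched HR/LR TIFF pairs plus a parameter record.

    Layout: ``out_dir/hr/img_###.tif`` and ``out_dir/lr/img_###.tif`` (the
    pairing convention the tiled datasets consume), with the degradation
    parameters recorded in ``out_dir/params.json`` as ground truth for
    noise-model recovery. LR images use the crappifier's fixed ``intensity``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True")
    (out_dir / "hr").mkdir(parents=True, exist_ok=True)
    (out_dir / "lr").mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence([seed, spec.seed])
    child_seeds = ss.generate_state(2 * n) % (2**31 - 1)
    record = {
        "n": n,
        "scale": scale,
        "crappifier": {
            "family": crappifier.family,
            "intensity": crappifier.intensity,
            "gain": crappifier.gain,
            "clip": crappifier.clip,
        },
        "specimen": {**asdict(spec), "shape": list(spec.shape)},
        "seed": seed,
        "images": [],
    }
    for i in range(n):
        sp = SpecimenSpec(
            shape=spec.shape,
            n_spots=spec.n_spots,
            n_filaments=spec.n_filaments,
            psf_sigma=spec.psf_sigma,
            background=spec.background,
            seed=int(child_seeds[2 * i]),
        )
        hr = generate_specimen(sp)
        lr = downsample(hr, scale)
        if crappifier.family != "none":
            lr = apply_noise(lr, crappifier, crappifier.intensity, int(child_seeds[2 * i + 1]))
            lr = lr.with_data(np.clip(lr.data, 0.0, 1.0))
        name = f"img_{i:03d}.tif"
        write_image(hr, out_dir / "hr" / name)
        write_image(lr, out_dir / "lr" / name)
        record["images"].append({"name": name, "specimen_seed": int(child_seeds[2 * i])})

    with open(out_dir / "params.json", "w") as fh:
        json.dump(record, fh, indent=2)
    return record
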