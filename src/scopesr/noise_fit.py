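"""Calibrating degradation parameters from real high/low-resolution pairs.

The noise in a true low-resolution acquisition is isolated by downsampling
its high-resolution counterpart to a "noiseless" low-resolution image and
subtracting that from the true acquisition, yielding a *noise profile* — a
signed residual array whose value distribution characterizes the detector
noise. Crappifier parameters are then fitted by minimizing the 1-Wasserstein
distance between the value distribution of the true noise profile and that of
profiles produced by candidate parameters, using Bayesian optimization with a
Gaussian-process surrogate (Matérn-5/2 kernel, expected-improvement
acquisition).

The objective is Monte-Carlo in nature (noise is sampled per candidate); one
shared noise seed is used for every candidate evaluation so the optimized
surface is quasi-deterministic, which GP surrogates assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, wasserstein_distance
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .crappify import Crappifier, apply_noise, downsample
from .image_io import ImageStack

__all__ = [
    "NoiseProfile",
    "CrappifierFit",
    "compute_noise_profile",
    "profile_distance",
    "fit_crappifier",
]

_MAX_PROFILE_VALUES = 100_000
_N_INITIAL = 10


@dataclass
class NoiseProfile:
    """Signed residuals (true LR minus downsampled HR), unclipped."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def std(self) -> float:
        return float(self.values.std())


@dataclass
class CrappifierFit:
    """Result of a noise-model fit."""

    family: str
    fitted_params: dict[str, float]
    objective: float
    n_evaluations: int
    trace: list[tuple[dict[str, float], float]] = field(default_factory=list)

    def best_crappifier(self, template: Crappifier | None = None) -> Crappifier:
        base = template or Crappifier(family=self.family)
        return base.with_params(**self.fitted_params)


def compute_noise_profile(hr: ImageStack, lr_true: ImageStack, scale: int) -> NoiseProfile:
    """Residual of the true LR image against the downsampled HR image."""
    lr_clean = downsample(hr, scale)
    if lr_clean.spatial_shape != lr_true.spatial_shape or lr_clean.shape != lr_true.shape:
        raise ValueError(
            f"downsampled HR shape {lr_clean.shape} does not match "
            f"true LR shape {lr_true.shape}"
        )
    return NoiseProfile(lr_true.data.astype(np.float64) - lr_clean.data.astype(np.float64))


def _subsample(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flat = values.ravel()
    if flat.size > _MAX_PROFILE_VALUES:
        idx = rng.choice(flat.size, _MAX_PROFILE_VALUES, replace=False)
        flat = flat[idx]
    return flat


def profile_distance(profile_a: NoiseProfile, profile_b: NoiseProfile) -> float:
    """1-Wasserstein distance between the two profiles' value distributions.

    Shapes need not match; the distance compares pooled values only. Zero iff
    the empirical distributions coincide; symmetric.
    """
    a, b = profile_a.values.ravel(), profile_b.values.ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("profiles must be nonempty")
    rng = np.random.default_rng(0)
    return float(wasserstein_distance(_subsample(a, rng), _subsample(b, rng)))


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def fit_crappifier(
    pairs: list[tuple[ImageStack, ImageStack]],
    family: str,
    bounds: dict[str, tuple[float, float]],
    n_calls: int = 40,
    rng_seed: int = 0,
    *,
    template: Crappifier | None = None,
) -> CrappifierFit:
    """Fit crappifier parameters to real HR/LR pairs by GP Bayesian optimization.

    Parameters
    ----------
    pairs:
        (hr, lr_true) image pairs; the downsampling factor is inferred from
        their spatial shape ratio.
    family:
        Noise family to fit.
    bounds:
        Search interval per parameter name (e.g. ``{"intensity": (0.0, 0.5)}``).
    n_calls:
        Total objective evaluations, including the 10-point random initial
        design.
    rng_seed:
        Seeds the initial design, the candidate sampling, and the single
        shared noise seed used by all candidate evaluations.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    if not bounds:
        raise ValueError("bounds must be nonempty")
    for name, (lo, hi) in bounds.items():
        if lo > hi:
            raise ValueError(f"bounds for {name!r}: low {lo} > high {hi}")
    if n_calls < _N_INITIAL:
        raise ValueError(f"n_calls must be >= {_N_INITIAL} (initial design size), got {n_calls}")

    hr0, lr0 = pairs[0]
    scale = hr0.spatial_shape[0] // lr0.spatial_shape[0]
    if scale < 1 or hr0.spatial_shape[0] != scale * lr0.spatial_shape[0]:
        raise ValueError(
            f"cannot infer integer scale from HR {hr0.spatial_shape} / LR {lr0.spatial_shape}"
        )

    base = (template or Crappifier(family=family)).with_params()
    base = Crappifier(family=family, intensity=base.intensity, gain=base.gain, clip=base.clip)
    names = sorted(bounds)
    lows = np.array([bounds[n][0] for n in names])
    highs = np.array([bounds[n][1] for n in names])

    rng = np.random.default_rng(rng_seed)
    noise_seed = int(rng.integers(0, 2**31 - 1))  # shared by every candidate
    sub_rng = np.random.default_rng(noise_seed)

    lr_cleans = [downsample(hr, scale) for hr, _ in pairs]
    true_profiles = [
        _subsample(compute_noise_profile(hr, lr, scale).values, sub_rng)
        for (hr, lr) in pairs
    ]

    def objective(x: np.ndarray) -> float:
        params = {n: float(v) for n, v in zip(names, x)}
        cand = base.with_params(**params)
        total = 0.0
        for (lr_clean, true_vals) in zip(lr_cleans, true_profiles):
            lr_syn = apply_noise(lr_clean, cand, cand.intensity, noise_seed)
            syn_vals = lr_syn.data.astype(np.float64) - lr_clean.data.astype(np.float64)
            total += wasserstein_distance(
                _subsample(syn_vals, np.random.default_rng(noise_seed)), true_vals
            )
        return total / len(pairs)

    span = np.where(highs > lows, highs - lows, 1.0)
    X: list[np.ndarray] = []
    y: list[float] = []
    trace: list[tuple[dict[str, float], float]] = []

    for _ in range(min(_N_INITIAL, n_calls)):
        x = rng.uniform(lows, highs)
        X.append(x)
        y.append(objective(x))
        trace.append(({n: float(v) for n, v in zip(names, x)}, y[-1]))

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.ones(len(names)), length_scale_bounds=(1e-3, 1e3), nu=2.5
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    for _ in range(n_calls - len(X)):
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(0, 2**31 - 1))
        )
        Xn = (np.array(X) - lows) / span
        with _warnings.catch_warnings():
            # near-noiseless objectives push the White kernel to its floor;
            # that is expected here, not a fit failure
            _warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xn, np.array(y))
        cand = rng.uniform(lows, highs, size=(512, len(names)))
        mu, sigma = gp.predict((cand - lows) / span, return_std=True)
        ei = _expected_improvement(mu, sigma, min(y))
        x = cand[int(np.argmax(ei))]
        X.append(x)
        y.append(objective(x))
        trace.append(({n: float(v) for n, v in zip(names, x)}, y[-1]))

    best_idx = int(np.argmin(y))
    return CrappifierFit(
        family=family,
        fitted_params={n: float(v) for n, v in zip(names, X[best_idx])},
        objective=float(y[best_idx]),
        n_evaluations=len(y),
        trace=trace,
    )
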