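"""Residual U-Net restoration models with configurable upsampling scale.

The architecture is an encoder/decoder with residual blocks at every level,
skip connections by channel concatenation, strided-convolution downsampling
and sub-pixel (pixel-shuffle) upsampling. When ``scale > 1`` a pixel-shuffle
head enlarges the output by the scale factor (super-resolution); at
``scale == 1`` the network is a pure denoiser. The network predicts a
*residual* against the nearest-neighbour upsampled input, so the identity
mapping is available from the first step of training.

Widths double per level from ``base_channels``; parameter shapes — and, with
a fixed seed, the initial values — are a pure function of the spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, ResBlock, Tensor, concat

__all__ = ["ModelSpec", "ResUNet", "build_resunet", "save_checkpoint", "load_checkpoint"]

_VALID_SCALES = (1, 2, 4, 8)


@dataclass
class ModelSpec:
    """Shape and size configuration for a residual U-Net.

    in_frames / out_frames allow asymmetric dimensionality: several adjacent
    frames (time points or z-slices) in, a single restored frame out. Scale 1
    yields a denoising model. Defaults are sized for desk-scale experiments;
    production presets simply raise ``base_channels`` and ``depth``.
    """

    in_frames: int = 1
    out_frames: int = 1
    scale: int = 2
    base_channels: int = 16
    depth: int = 3

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ValueError(f"scale must be one of {_VALID_SCALES}, got {self.scale}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.in_frames < 1 or self.out_frames < 1:
            raise ValueError("in_frames and out_frames must be >= 1")


class ResUNet(Module):
    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        ch = spec.base_channels
        self.stem = Conv2d(spec.in_frames, ch, rng=rng)

        self.enc_blocks: list[Module] = []
        self.downs: list[Module] = []
        widths = [ch * 2**i for i in range(spec.depth)]
        for wdt in widths:
            self.enc_blocks.append(ResBlock(wdt, rng=rng))
            self.downs.append(Conv2d(wdt, wdt * 2, stride=2, rng=rng))
        self.bottleneck = ResBlock(widths[-1] * 2, rng=rng)

        self.up_convs: list[Module] = []
        self.dec_fuse: list[Module] = []
        self.dec_blocks: list[Module] = []
        for wdt in reversed(widths):
            # pixel-shuffle upsampling: conv to 4x target width, shuffle r=2
            self.up_convs.append(Conv2d(wdt * 2, wdt * 4, rng=rng))
            self.dec_fuse.append(Conv2d(wdt * 2, wdt, rng=rng))
            self.dec_blocks.append(ResBlock(wdt, rng=rng))

        head_out = spec.out_frames * spec.scale * spec.scale
        self.head = Conv2d(ch, head_out, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        spec = self.spec
        n, c, h, w = x.data.shape
        if c != spec.in_frames:
            raise ValueError(f"expected {spec.in_frames} input frames, got {c}")
        div = 2**spec.depth
        if h % div or w % div:
            raise ValueError(
                f"spatial extents ({h}, {w}) must be divisible by 2^depth = {div}"
            )

        feat = self.stem(x).relu()
        skips = []
        for block, down in zip(self.enc_blocks, self.downs):
            feat = block(feat)
            skips.append(feat)
            feat = down(feat).relu()
        feat = self.bottleneck(feat)
        for up, fuse, block, skip in zip(
            self.up_convs, self.dec_fuse, self.dec_blocks, reversed(skips)
        ):
            feat = up(feat).pixel_shuffle(2).relu()
            feat = fuse(concat([feat, skip], axis=1)).relu()
            feat = block(feat)
        out = self.head(feat)
        if spec.scale > 1:
            out = out.pixel_shuffle(spec.scale)
        # global residual against the upsampled center input frame
        center = spec.in_frames // 2
        base = Tensor(
            x.data[:, center : center + 1, :, :].repeat(spec.out_frames, axis=1),
            requires_grad=False,
        )
        if spec.scale > 1:
            base = base.upsample_nearest(spec.scale)
        return out + base

    def predict(self, frames: np.ndarray) -> np.ndarray:
        """Convenience inference on a (N, in_frames, H, W) float array."""
        return self.forward(Tensor(frames)).data


def build_resunet(spec: ModelSpec, seed: int = 0) -> ResUNet:
    """Construct a residual U-Net with deterministic seeded initialization."""
    return ResUNet(spec, seed=seed)


def save_checkpoint(model: ResUNet, path) -> None:
    """Save weights plus the model spec in a single npz container."""
    spec = model.spec
    meta = np.array(
        [spec.in_frames, spec.out_frames, spec.scale, spec.base_channels, spec.depth],
        dtype=np.int64,
    )
    np.savez(path, __spec__=meta, **model.state_dict())


def load_checkpoint(path) -> ResUNet:
    with np.load(path) as data:
        meta = data["__spec__"]
        spec = ModelSpec(
            in_frames=int(meta[0]),
            out_frames=int(meta[1]),
            scale=int(meta[2]),
            base_channels=int(meta[3]),
            depth=int(meta[4]),
        )
        model = ResUNet(spec, seed=0)
        model.load_state_dict({k: v for k, v in data.items() if k != "__spec__"})
    return model
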