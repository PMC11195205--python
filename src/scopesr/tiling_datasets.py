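"""Tiled datasets with leakage-safe splitting and runtime crappification.

Large micrographs are divided into square spatial tiles on a regular grid;
every combination of non-spatial indices (time, depth, channel) of a tile
becomes a separate *frame* of the same tile. Because frames of one tile are
often nearly identical, train/validation splitting assigns whole tiles, never
individual frames — otherwise near-duplicates leak across the split and
validation loss underestimates generalization error.

Three dataset modes cover the workflow:

``train_crappified``
    Items are HR tiles; the low-resolution input is regenerated at access
    time by the crappifier with a seed derived from (epoch, index), so each
    epoch sees a fresh random degradation of every tile.
``predict_lr_only``
    Items are LR tiles with no target (restoration of real acquisitions).
``benchmark_paired``
    Items are aligned true LR / HR image pairs with no crappification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .crappify import Crappifier, IntensityRange, crappify
from .image_io import ImageStack, read_image

__all__ = [
    "TileIndex",
    "SlideConfig",
    "tile_image",
    "split_by_tile",
    "stitch_tiles",
    "TiledDataset",
    "load_image_dir",
]

MODES = ("train_crappified", "predict_lr_only", "benchmark_paired")


@dataclass(frozen=True, order=True)
class TileIndex:
    """Identity of one dataset item: which image, which grid cell, which frame."""

    image_id: str
    tile_pos: tuple[int, int]
    frame: int = 0

    @property
    def tile_key(self) -> tuple[str, tuple[int, int]]:
        """Leakage unit: all frames of a tile share this key."""
        return (self.image_id, self.tile_pos)


@dataclass
class SlideConfig:
    """Square sliding-tile geometry.

    stride = tile_size - overlap. ``boundary`` controls partial tiles at the
    right/bottom edges: ``drop`` discards them (training default, avoids pad
    artifacts in targets), ``pad_reflect`` reflect-pads the image so the last
    grid row/column is included (prediction default, full coverage).
    """

    tile_size: int
    overlap: int = 0
    boundary: str = "drop"

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError(f"tile_size must be positive, got {self.tile_size}")
        if not 0 <= self.overlap < self.tile_size:
            raise ValueError(
                f"overlap must satisfy 0 <= overlap < tile_size, got {self.overlap}"
            )
        if self.boundary not in ("drop", "pad_reflect"):
            raise ValueError(f"boundary must be 'drop' or 'pad_reflect', got {self.boundary!r}")

    @property
    def stride(self) -> int:
        return self.tile_size - self.overlap


def _grid_counts(extent: int, config: SlideConfig) -> int:
    if config.boundary == "drop":
        if extent < config.tile_size:
            return 0
        return (extent - config.tile_size) // config.stride + 1
    # pad_reflect: enough grid positions that tiles cover the full extent
    return max(1, -(-(extent - config.tile_size) // config.stride) + 1)


def _pad_for_grid(extent: int, config: SlideConfig) -> int:
    n = _grid_counts(extent, config)
    return max(0, (n - 1) * config.stride + config.tile_size - extent)


def tile_image(
    stack: ImageStack, config: SlideConfig, image_id: str = "image"
) -> list[tuple[TileIndex, ImageStack]]:
    """Cut an image into (TileIndex, 2-D tile) items on a regular grid.

    Each non-spatial index combination of a grid cell becomes a distinct
    frame of the same tile position. Coordinates are 0-based; a tile at grid
    position (r, c) covers the half-open box
    ``[r*stride, r*stride + tile_size) x [c*stride, ...)``.
    """
    h, w = stack.spatial_shape
    ny, nx = _grid_counts(h, config), _grid_counts(w, config)
    if ny == 0 or nx == 0:
        raise ValueError(
            f"tile_size {config.tile_size} exceeds image extents ({h}, {w}) "
            "with boundary='drop'"
        )
    frames = stack.frames()
    if config.boundary == "pad_reflect":
        py, px = _pad_for_grid(h, config), _pad_for_grid(w, config)
        if py or px:
            frames = np.pad(frames, ((0, 0), (0, py), (0, px)), mode="reflect")

    out: list[tuple[TileIndex, ImageStack]] = []
    ts, stride = config.tile_size, config.stride
    for r in range(ny):
        for c in range(nx):
            y0, x0 = r * stride, c * stride
            block = frames[:, y0 : y0 + ts, x0 : x0 + ts]
            for f in range(block.shape[0]):
                out.append(
                    (
                        TileIndex(image_id, (r, c), f),
                        ImageStack(block[f].copy(), "YX", stack.source_dtype),
                    )
                )
    return out


def split_by_tile(
    indices: Iterable[TileIndex], val_fraction: float, rng_seed: int
) -> tuple[list[TileIndex], list[TileIndex]]:
    """Split items into train/validation by whole tiles.

    Distinct (image_id, tile_pos) keys are shuffled with the seed;
    ``round(val_fraction * n_keys)`` keys form the validation set, and every
    frame follows its tile's assignment. The two sets partition the input at
    the tile level.
    """
    indices = list(indices)
    if not indices:
        raise ValueError("indices must be nonempty")
    if not 0.0 <= val_fraction <= 1.0:
        raise ValueError(f"val_fraction must be in [0, 1], got {val_fraction}")
    keys = sorted({ti.tile_key for ti in indices})
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(keys))
    n_val = round(val_fraction * len(keys))
    val_keys = {keys[i] for i in order[:n_val]}
    train = [ti for ti in indices if ti.tile_key not in val_keys]
    val = [ti for ti in indices if ti.tile_key in val_keys]
    return train, val


def stitch_tiles(
    tiles: list[tuple[TileIndex, ImageStack]],
    original_shape: tuple[int, ...],
    config: SlideConfig,
) -> ImageStack:
    """Reassemble tiles produced by :func:`tile_image` into one image.

    Overlapping regions are averaged with equal weight; the grid produced by
    ``tile_image(stack, config)`` round-trips exactly on non-padded regions.
    """
    h, w = original_shape[-2], original_shape[-1]
    n_frames = int(np.prod(original_shape[:-2], dtype=np.int64)) if len(original_shape) > 2 else 1
    ny, nx = _grid_counts(h, config), _grid_counts(w, config)
    py = _pad_for_grid(h, config) if config.boundary == "pad_reflect" else 0
    px = _pad_for_grid(w, config) if config.boundary == "pad_reflect" else 0

    expected = {(r, c) for r in range(ny) for c in range(nx)}
    present = {ti.tile_pos for ti, _ in tiles}
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"missing grid positions: {missing}")

    acc = np.zeros((n_frames, h + py, w + px), dtype=np.float64)
    weight = np.zeros((1, h + py, w + px), dtype=np.float64)
    ts, stride = config.tile_size, config.stride
    source_dtype = tiles[0][1].source_dtype
    for ti, tile in tiles:
        r, c = ti.tile_pos
        y0, x0 = r * stride, c * stride
        acc[ti.frame, y0 : y0 + ts, x0 : x0 + ts] += tile.data
        if ti.frame == 0:
            weight[0, y0 : y0 + ts, x0 : x0 + ts] += 1.0
    weight = np.maximum(weight, 1.0)
    out = (acc / weight)[:, :h, :w].astype(np.float32)
    axes = "YX" if len(original_shape) == 2 else ("T" + "YX" if len(original_shape) == 3 else "TZYX")
    return ImageStack(out.reshape(original_shape), axes, source_dtype)


def load_image_dir(path: str | Path, axes_hint: str | None = None) -> dict[str, ImageStack]:
    """Read every TIFF in a directory, keyed by filename (sorted order)."""
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise FileNotFoundError(f"no TIFF files in {path}")
    return {p.name: read_image(p, axes_hint) for p in files}


class TiledDataset:
    """Dataset of tile frames in one of the three workflow modes.

    Parameters
    ----------
    sources:
        Mapping image_id -> ImageStack. For ``train_crappified`` these are HR
        images; for ``predict_lr_only``, LR images; for ``benchmark_paired``,
        HR images (with ``lr_sources`` holding the aligned LR counterparts,
        matched by identical keys).
    config:
        Tile geometry. In ``benchmark_paired`` mode whole images are used as
        single tiles and ``config`` may be None.
    mode:
        One of ``train_crappified``, ``predict_lr_only``, ``benchmark_paired``.
    scale, crappifier, intensity_range:
        Degradation settings (required in ``train_crappified`` mode).
    indices:
        Optional explicit item list (e.g. one side of ``split_by_tile``);
        defaults to all tiles of all sources in deterministic order.
    in_frame_window:
        Odd window of adjacent frames supplied as model input around each
        target frame (asymmetric input/output dimensionality). Frame indices
        reflect at the ends of the stack. Default 1 (single frame in/out).
    """

    def __init__(
        self,
        sources: Mapping[str, ImageStack],
        config: SlideConfig | None,
        mode: str,
        *,
        scale: int = 1,
        crappifier: Crappifier | None = None,
        intensity_range: IntensityRange | None = None,
        lr_sources: Mapping[str, ImageStack] | None = None,
        indices: list[TileIndex] | None = None,
        in_frame_window: int = 1,
    ) -> None:
        if in_frame_window < 1 or in_frame_window % 2 == 0:
            raise ValueError(f"in_frame_window must be a positive odd integer, got {in_frame_window}")
        self.in_frame_window = in_frame_window
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        if mode == "train_crappified":
            if crappifier is None:
                raise ValueError("train_crappified mode requires a crappifier")
            if intensity_range is None:
                intensity_range = IntensityRange(crappifier.intensity, crappifier.intensity)
        if mode == "benchmark_paired":
            if lr_sources is None:
                raise ValueError("benchmark_paired mode requires lr_sources")
            if set(lr_sources) != set(sources):
                raise ValueError(
                    "benchmark_paired HR and LR sources must share identical image ids"
                )
        self.mode = mode
        self.scale = int(scale)
        self.crappifier = crappifier
        self.intensity_range = intensity_range
        self.lr_sources = dict(lr_sources) if lr_sources else None
        self.sources = dict(sources)

        self._tiles: dict[TileIndex, ImageStack] = {}
        if mode == "benchmark_paired" or config is None:
            # whole images as single tiles
            for image_id in sorted(self.sources):
                stack = self.sources[image_id]
                frames = stack.frames()
                for f in range(frames.shape[0]):
                    ti = TileIndex(image_id, (0, 0), f)
                    self._tiles[ti] = ImageStack(frames[f], "YX", stack.source_dtype)
        else:
            for image_id in sorted(self.sources):
                for ti, tile in tile_image(self.sources[image_id], config, image_id):
                    self._tiles[ti] = tile
        self.config = config
        self.indices: list[TileIndex] = (
            list(indices) if indices is not None else sorted(self._tiles)
        )
        for ti in self.indices:
            if ti not in self._tiles:
                raise ValueError(f"index {ti} not present in tiled sources")

    def __len__(self) -> int:
        return len(self.indices)

    def subset(self, indices: list[TileIndex]) -> "TiledDataset":
        clone = object.__new__(TiledDataset)
        clone.__dict__ = {**self.__dict__, "indices": list(indices)}
        for ti in indices:
            if ti not in self._tiles:
                raise ValueError(f"index {ti} not present in tiled sources")
        return clone

    def get_item(
        self, index: int, epoch_seed: int = 0
    ) -> tuple[ImageStack, ImageStack | None]:
        """Return (input, target) for one item.

        ``train_crappified``: target is the HR tile frame and the input is a
        fresh crappification seeded by (epoch_seed, index), so each epoch
        degrades the same tile differently. ``predict_lr_only``: (LR, None).
        ``benchmark_paired``: the true (LR, HR) pair, untouched.
        """
        if not 0 <= index < len(self.indices):
            raise IndexError(f"index {index} out of range for dataset of {len(self)}")
        ti = self.indices[index]
        tile = self._tiles[ti]
        if self.mode == "predict_lr_only":
            return self._with_frame_window(ti), None
        if self.mode == "benchmark_paired":
            lr_stack = self.lr_sources[ti.image_id]
            lr_frames = lr_stack.frames()
            lr = ImageStack(lr_frames[ti.frame], "YX", lr_stack.source_dtype)
            return lr, tile
        seed = int(
            np.random.SeedSequence([epoch_seed & 0x7FFFFFFF, index]).generate_state(1)[0]
            % (2**31 - 1)
        )
        source = self._with_frame_window(ti)
        lr_noisy, _ = crappify(source, self.scale, self.crappifier, self.intensity_range, seed)
        return lr_noisy, tile

    def _n_frames_of(self, image_id: str) -> int:
        return self.sources[image_id].n_frames

    def _with_frame_window(self, ti: TileIndex) -> ImageStack:
        """Tile frames in a reflected window centered on ti.frame (axes TYX)."""
        if self.in_frame_window == 1:
            return self._tiles[ti]
        half = self.in_frame_window // 2
        n = self._n_frames_of(ti.image_id)
        frames = []
        for off in range(-half, half + 1):
            f = ti.frame + off
            if f < 0:
                f = -f
            if f >= n:
                f = 2 * (n - 1) - f
            f = int(np.clip(f, 0, n - 1))
            frames.append(self._tiles[TileIndex(ti.image_id, ti.tile_pos, f)].data)
        stack = np.stack(frames)
        return ImageStack(stack, "TYX", self._tiles[ti].source_dtype)
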