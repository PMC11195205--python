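"""Reading and writing n-dimensional grayscale microscopy images.

Images move through the pipeline as :class:`ImageStack`: a float array in the
canonical range [0, 1] with explicit axis-role labels drawn from ``TZCYX``
(time, depth, channel, row, column). ``Y`` and ``X`` are always the last two
axes. The original unsigned integer storage type is retained so images can be
written back at their native bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

VALID_AXES = "TZCYX"

__all__ = ["ImageStack", "read_image", "write_image", "VALID_AXES"]


class FormatError(ValueError):
    """Raised when a file's contents cannot be mapped onto an ImageStack."""


@dataclass
class ImageStack:
    """An n-dimensional grayscale image with axis-role labels.

    Parameters
    ----------
    data:
        Intensity array, canonically in [0, 1]. Stored as float32.
    axes:
        One label per axis from ``TZCYX``; ``Y`` and ``X`` mandatory and last.
    source_dtype:
        Unsigned integer dtype of the originating file (uint8 or uint16),
        used to quantize values on write. Defaults to uint16.
    """

    data: np.ndarray
    axes: str = "YX"
    source_dtype: np.dtype = field(default_factory=lambda: np.dtype(np.uint16))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.source_dtype = np.dtype(self.source_dtype)
        if self.source_dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
            raise ValueError(f"source_dtype must be uint8 or uint16, got {self.source_dtype}")
        if len(self.axes) != self.data.ndim:
            raise ValueError(
                f"axes {self.axes!r} has {len(self.axes)} labels for a {self.data.ndim}-d array"
            )
        if len(set(self.axes)) != len(self.axes):
            raise ValueError(f"duplicate axis labels in {self.axes!r}")
        if any(a not in VALID_AXES for a in self.axes):
            raise ValueError(f"axis labels must be drawn from {VALID_AXES!r}, got {self.axes!r}")
        if not self.axes.endswith("YX"):
            raise ValueError(f"Y and X must be the final two axes, got {self.axes!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    @property
    def n_frames(self) -> int:
        """Product of all non-spatial extents (1 for a plain 2-D image)."""
        return int(np.prod(self.data.shape[:-2], dtype=np.int64)) if self.data.ndim > 2 else 1

    def frames(self) -> np.ndarray:
        """View of the data with non-spatial axes flattened: (frames, Y, X)."""
        h, w = self.spatial_shape
        return self.data.reshape(self.n_frames, h, w)

    def with_data(self, data: np.ndarray, axes: str | None = None) -> "ImageStack":
        return ImageStack(data, axes if axes is not None else self.axes, self.source_dtype)


def _default_axes(ndim: int) -> str:
    # Unknown leading axes default to T then Z (fixed convention so configs
    # stay portable across files with absent or nonstandard TIFF metadata).
    if ndim == 2:
        return "YX"
    if ndim == 3:
        return "TYX"
    if ndim == 4:
        return "TZYX"
    raise FormatError(f"cannot assign default axis roles to a {ndim}-d image")


def read_image(path: str | Path, axes_hint: str | None = None) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an ImageStack.

    Values are normalized to [0, 1] by dividing by the maximum representable
    value of the file's dtype. Axis roles come from ``axes_hint`` when given,
    else from TIFF metadata when it uses the ``TZCYX`` vocabulary, else from
    the default convention (leading axes labelled T then Z).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            meta_axes = series.axes
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-TIFF
        raise OSError(f"cannot read TIFF image {path}: {exc}") from exc

    data = np.squeeze(data)
    if data.ndim < 2:
        raise FormatError(f"{path}: image has fewer than 2 dimensions")
    if data.dtype == np.uint8:
        source_dtype = np.dtype(np.uint8)
    elif data.dtype == np.uint16:
        source_dtype = np.dtype(np.uint16)
    else:
        raise FormatError(f"{path}: unsupported dtype {data.dtype}; expected uint8 or uint16")

    if axes_hint is not None:
        if len(axes_hint) != data.ndim:
            raise ValueError(
                f"axes_hint {axes_hint!r} has {len(axes_hint)} labels but image at {path} "
                f"has {data.ndim} dimensions"
            )
        axes = axes_hint
    else:
        meta = "".join(a for a in meta_axes if a in VALID_AXES)
        if len(meta) == data.ndim and meta.endswith("YX") and len(set(meta)) == len(meta):
            axes = meta
        else:
            axes = _default_axes(data.ndim)

    max_val = np.float32(np.iinfo(source_dtype).max)
    return ImageStack(data.astype(np.float32) / max_val, axes, source_dtype)


def write_image(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as a TIFF at its source bit depth.

    Values are rescaled to the full range of ``source_dtype`` with rounding;
    a multi-page file is produced when non-spatial axes are present.
    """
    path = Path(path)
    data = stack.data
    if data.min() < 0.0 or data.max() > 1.0:
        raise ValueError(
            f"values outside [0, 1] (min {data.min():.4g}, max {data.max():.4g}); "
            "clip before writing"
        )
    max_val = np.iinfo(stack.source_dtype).max
    quantized = np.round(data.astype(np.float64) * max_val).astype(stack.source_dtype)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, quantized, photometric="minisblack")
    return path
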