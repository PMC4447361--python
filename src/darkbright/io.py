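"""Reading and writing calibrated luminance images and distance maps.

Supported rasters: headerless 16-bit IML files (a raw plane of unsigned
integers, big-endian by convention), TIFF via :mod:`tifffile`, NumPy
``.npy`` arrays, and whitespace-delimited text matrices.  Distance maps are
single-plane float rasters with a declared missing-value sentinel.

Luminance is kept in linear, arbitrary calibrated units; the downstream
contrast operators divide by local luminance, so any global calibration
scale cancels.  A per-image ``calibration`` hook (scale/offset or an
arbitrary callable) is provided for datasets that ship a camera transfer
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "LuminanceImage",
    "DistanceMap",
    "read_iml",
    "write_iml",
    "rgb_to_gray",
    "read_raster",
    "read_depth_pair",
]

#: Weights of the standard RGB -> gray conversion.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class LuminanceImage:
    """A calibrated, linear luminance image.

    Parameters
    ----------
    values
        2-D array of nonnegative luminance in arbitrary calibrated units.
    pixel_size
        Angular width of one pixel in arcminutes (> 0).
    source_id
        Free-text provenance tag.
    """

    values: np.ndarray
    pixel_size: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("luminance values must be a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("luminance values must be finite")
        if np.any(self.values < 0):
            raise ValueError("luminance values must be >= 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0 arcmin")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DistanceMap:
    """Per-pixel scene distances in meters with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray | None = None
    pixel_size: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("distance values must be a 2-D array")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values) & (self.values > 0)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask shape must match values")
        valid = self.values[self.valid_mask]
        if valid.size and not (np.all(np.isfinite(valid)) and np.all(valid > 0)):
            raise ValueError("distances must be finite and > 0 where valid")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0 arcmin")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _apply_calibration(counts: np.ndarray, calibration) -> np.ndarray:
    """Apply a pluggable counts -> luminance calibration.

    ``calibration`` may be ``None`` (identity on raw counts), a
    ``(scale, offset)`` pair giving ``scale * counts + offset``, or a
    callable mapping the count array to luminance.
    """
    if calibration is None:
        return np.asarray(counts, dtype=float)
    if callable(calibration):
        return np.asarray(calibration(counts), dtype=float)
    scale, offset = calibration
    return scale * np.asarray(counts, dtype=float) + offset


def read_iml(
    path,
    width: int = 1536,
    height: int = 1024,
    *,
    pixel_size: float = 1.0,
    byte_order: str = ">",
    calibration=None,
) -> LuminanceImage:
    """Read a headerless 16-bit unsigned-integer raster (IML format).

    The file must contain exactly ``width * height`` 16-bit samples in
    row-major order.  ``byte_order`` is ``">"`` (big-endian, the dataset's
    native convention) or ``"<"``.  Pixel size defaults to 1 arcmin.
    """
    if byte_order not in (">", "<"):
        raise ValueError("byte_order must be '>' or '<'")
    raw = Path(path).read_bytes()
    expected = width * height * 2
    if len(raw) != expected:
        raise ValueError(
            f"IML file {path}: expected {expected} bytes "
            f"({width}x{height} 16-bit samples), got {len(raw)}"
        )
    counts = np.frombuffer(raw, dtype=np.dtype(byte_order + "u2"))
    counts = counts.reshape(height, width)
    return LuminanceImage(
        _apply_calibration(counts, calibration),
        pixel_size=pixel_size,
        source_id=str(path),
    )


def write_iml(image: LuminanceImage | np.ndarray, path, *, byte_order: str = ">") -> None:
    """Write a raster as headerless 16-bit unsigned integers.

    Values must already lie in [0, 65535]; they are rounded to the nearest
    integer so that ``write_iml(read_iml(f))`` is byte-identical to ``f``.
    """
    if byte_order not in (">", "<"):
        raise ValueError("byte_order must be '>' or '<'")
    values = image.values if isinstance(image, LuminanceImage) else np.asarray(image)
    if np.any(values < 0) or np.any(values > 65535):
        raise ValueError("values outside the 16-bit range cannot be written")
    counts = np.round(values).astype(np.dtype(byte_order + "u2"))
    Path(path).write_bytes(counts.tobytes())


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Convert a 3-channel image to gray as 0.299 r + 0.587 g + 0.114 b.

    Accepts ``(H, W, 3)`` arrays; returns an ``(H, W)`` float array.  The
    conversion is linear in each channel.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    wr, wg, wb = GRAY_WEIGHTS
    return wr * r + wg * g + wb * b


def read_raster(path, *, pixel_size: float = 1.0, calibration=None, **iml_kwargs) -> LuminanceImage:
    """Read any supported raster as a :class:`LuminanceImage`.

    Dispatches on extension: ``.iml`` (raw 16-bit), ``.tif``/``.tiff``,
    ``.npy``, and ``.txt``/``.csv`` text matrices.  Color TIFFs are
    converted to gray with :func:`rgb_to_gray`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".iml":
        return read_iml(path, pixel_size=pixel_size, calibration=calibration, **iml_kwargs)
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    elif suffix == ".npy":
        arr = np.load(path).astype(float)
    elif suffix in (".txt", ".csv"):
        arr = np.loadtxt(path, delimiter="," if suffix == ".csv" else None)
    else:
        raise ValueError(f"unsupported raster format: {path}")
    if arr.ndim == 3:
        arr = rgb_to_gray(arr)
    return LuminanceImage(
        _apply_calibration(arr, calibration), pixel_size=pixel_size, source_id=str(path)
    )


def read_depth_pair(
    image_path,
    distance_path,
    *,
    pixel_size: float = 3.0,
    missing_value: float | None = None,
    calibration=None,
) -> tuple[LuminanceImage, DistanceMap]:
    """Read a paired luminance image and distance map.

    Distances equal to ``missing_value`` (plus any non-finite or
    nonpositive entries) are flagged in ``valid_mask`` rather than being
    zero-filled.  Shapes must match exactly.  Pixel size defaults to the
    3 arcmin typical of laser range-scanner image sets.
    """
    image = read_raster(image_path, pixel_size=pixel_size, calibration=calibration)
    dpath = Path(distance_path)
    suffix = dpath.suffix.lower()
    if suffix == ".npy":
        dist = np.load(dpath).astype(float)
    elif suffix in (".txt", ".csv"):
        dist = np.loadtxt(dpath, delimiter="," if suffix == ".csv" else None)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        dist = np.asarray(tifffile.imread(dpath), dtype=float)
    else:
        raise ValueError(f"unsupported distance raster format: {dpath}")
    if dist.shape != image.shape:
        raise ValueError(
            f"distance map shape {dist.shape} does not match image {image.shape}"
        )
    valid = np.isfinite(dist) & (dist > 0)
    if missing_value is not None:
        valid &= dist != missing_value
    return image, DistanceMap(dist, valid_mask=valid, pixel_size=pixel_size)
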