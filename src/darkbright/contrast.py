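"""Normalized difference-of-Gaussians contrast operators.

A contrast operator is a zero-sum DOG (unit-sum center minus unit-sum
surround) whose response is divided by the output of a third, unit-sum
normalizing Gaussian the size of the surround::

    c(x, y) = (g_c * L - g_s * L) / (g_n * L)

so the raw response behaves like a local percent contrast and is invariant
to global luminance scaling.  Raw responses are converted to *equivalent
contrast* -- the Weber or Michelson contrast of a calibration spot (a
uniform disc the size of the DOG positive lobe's FWHM on a 0.5 background)
that would produce the same center-pixel response -- via a lookup table
with linear interpolation, clamped to +/-100%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve

from .io import LuminanceImage

__all__ = [
    "DogSpec",
    "LookupTable",
    "ContrastOperator",
    "ContrastMap",
    "make_operator",
    "apply_operator",
    "build_lookup",
    "to_equivalent_contrast",
    "weber_lowpass_contrast",
    "split_bright_dark",
    "disc_mask",
    "gaussian_kernel_1d",
    "dog_fwhm",
]

#: Kernels are truncated at this many surround standard deviations.
KERNEL_EXTENT_SIGMAS = 4.0
#: Number of spot luminances in the calibration lookup grid.
LOOKUP_GRID_POINTS = 1001


@dataclass(frozen=True)
class DogSpec:
    """Geometry of a DOG contrast operator, in arcminutes.

    ``sigma_n`` (the normalizer) defaults to the surround size.
    """

    sigma_c: float
    sigma_s: float
    sigma_n: float | None = None

    def __post_init__(self):
        if not 0 < self.sigma_c < self.sigma_s:
            raise ValueError("require 0 < sigma_c < sigma_s")
        if self.sigma_n is None:
            object.__setattr__(self, "sigma_n", self.sigma_s)
        if not self.sigma_n > 0:
            raise ValueError("sigma_n must be > 0")


@dataclass
class LookupTable:
    """Monotone map between raw filter responses and percent contrasts."""

    responses: np.ndarray
    contrasts: np.ndarray

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        if self.responses.shape != self.contrasts.shape or self.responses.ndim != 1:
            raise ValueError("responses and contrasts must be matching 1-D arrays")
        if np.any(np.diff(self.responses) <= 0) or np.any(np.diff(self.contrasts) <= 0):
            raise ValueError("lookup table must be strictly increasing")


@dataclass
class ContrastOperator:
    """A discretized DOG contrast operator with its calibration tables."""

    spec: DogSpec
    pixel_size: float
    kernel_center: np.ndarray
    kernel_surround: np.ndarray
    kernel_normalizer: np.ndarray
    fwhm_positive_lobe: float  # arcmin
    lookup_weber: LookupTable | None = None
    lookup_michelson: LookupTable | None = None

    @property
    def kernel_dog(self) -> np.ndarray:
        return self.kernel_center - self.kernel_surround

    @property
    def half_width(self) -> int:
        """Half the kernel side in pixels; the crop margin after filtering."""
        return self.kernel_center.shape[0] // 2

    def lookup(self, definition: str) -> LookupTable:
        table = {"weber": self.lookup_weber, "michelson": self.lookup_michelson}[definition]
        if table is None:
            raise ValueError(f"no {definition} lookup table built for this operator")
        return table


@dataclass
class ContrastMap:
    """Per-pixel signed contrast values (raw or equivalent percent)."""

    values: np.ndarray
    definition: str  # "raw" | "weber" | "michelson"
    pixel_size: float
    clamped_fraction: float = 0.0
    meta: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.definition not in ("raw", "weber", "michelson"):
            raise ValueError("definition must be raw, weber or michelson")

    def save(self, path) -> None:
        """Write the raster (.npy) plus a JSON sidecar of its metadata."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        sidecar = {
            "definition": self.definition,
            "pixel_size": self.pixel_size,
            "clamped_fraction": self.clamped_fraction,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def gaussian_kernel_1d(sigma_px: float, half_width: int, oversample: int = 1) -> np.ndarray:
    """Sample a 1-D Gaussian on the pixel grid and renormalize to unit sum.

    With ``oversample > 1`` each pixel's weight is the average of
    ``oversample`` sub-pixel samples, which keeps under-sampled kernels
    (sigma around one pixel) close to their continuous profile.
    """
    x = np.arange(-half_width, half_width + 1, dtype=float)
    if oversample > 1:
        offsets = (np.arange(oversample) + 0.5) / oversample - 0.5
        x = x[:, None] + offsets[None, :]
    k = np.exp(-0.5 * (x / sigma_px) ** 2)
    if oversample > 1:
        k = k.mean(axis=1)
    return k / k.sum()


def dog_fwhm(sigma_c: float, sigma_s: float) -> float:
    """Diameter of the DOG positive lobe at half maximum (same units as sigma).

    Uses the continuous radial profile of the unit-volume 2-D Gaussians,
    ``p(r) = G(r; sigma_c) - G(r; sigma_s)``, and solves ``p(r) = p(0)/2``
    between the center and the zero crossing.
    """

    def profile(r):
        return (
            np.exp(-0.5 * (r / sigma_c) ** 2) / (2 * np.pi * sigma_c**2)
            - np.exp(-0.5 * (r / sigma_s) ** 2) / (2 * np.pi * sigma_s**2)
        )

    p0 = profile(0.0)
    # radius where the DOG changes sign
    r_zero = np.sqrt(
        2 * np.log(sigma_s**2 / sigma_c**2) * sigma_c**2 * sigma_s**2 / (sigma_s**2 - sigma_c**2)
    )
    r_half = brentq(lambda r: profile(r) - p0 / 2, 0.0, r_zero)
    return 2.0 * r_half


def disc_mask(half_width: int, radius_px: float) -> np.ndarray:
    """Pixel-center membership mask of a centered disc on a (2h+1)^2 grid."""
    x = np.arange(-half_width, half_width + 1, dtype=float)
    r = np.hypot(x[:, None], x[None, :])
    return r <= radius_px


def make_operator(
    spec: DogSpec,
    pixel_size: float = 1.0,
    definition: str = "weber",
    *,
    oversample: int = 1,
    build_lookups: bool = True,
) -> ContrastOperator:
    """Discretize a DOG contrast operator and build its calibration tables.

    All three Gaussians are sampled on a square grid of half-width
    ``4 * sigma_s`` pixels and renormalized to exact unit sum, so the DOG
    is exactly zero sum on the discrete grid.  ``definition`` selects which
    lookup is considered primary; both Weber and Michelson tables are built.
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    sc, ss, sn = (s / pixel_size for s in (spec.sigma_c, spec.sigma_s, spec.sigma_n))
    if sc < 1.0 and oversample == 1:
        warnings.warn(
            f"center sigma ({sc:.2f} px) is under-sampled on this grid; "
            "consider oversample > 1",
            stacklevel=2,
        )
    half_width = int(np.ceil(KERNEL_EXTENT_SIGMAS * ss))
    k1 = {s: gaussian_kernel_1d(s, half_width, oversample) for s in (sc, ss, sn)}
    op = ContrastOperator(
        spec=spec,
        pixel_size=pixel_size,
        kernel_center=np.outer(k1[sc], k1[sc]),
        kernel_surround=np.outer(k1[ss], k1[ss]),
        kernel_normalizer=np.outer(k1[sn], k1[sn]),
        fwhm_positive_lobe=dog_fwhm(spec.sigma_c, spec.sigma_s),
    )
    if build_lookups:
        op.lookup_weber = build_lookup(op, "weber")
        op.lookup_michelson = build_lookup(op, "michelson")
    return op


def build_lookup(op: ContrastOperator, definition: str) -> LookupTable:
    """Calibrate raw responses against spot stimuli of known contrast.

    Spots are uniform discs with diameter equal to the DOG positive lobe's
    FWHM, rasterized by pixel-center membership, on a uniform background of
    0.5, with spot luminances on a dense grid in [0, 1].  The recorded
    response is the operator's center-pixel response to each spot; the
    paired contrast is the spot's Weber ``(s-b)/b`` or Michelson
    ``(s-b)/(s+b)`` contrast in percent.

    Because the stimulus is ``0.5 + (s - 0.5) * disc``, the center-pixel
    numerator and denominator are affine in ``s`` and the full response
    curve follows from two kernel/disc inner products; this is identical to
    filtering each spot image and reading the center pixel.
    """
    if definition not in ("weber", "michelson"):
        raise ValueError("definition must be 'weber' or 'michelson'")
    radius_px = 0.5 * op.fwhm_positive_lobe / op.pixel_size
    disc = disc_mask(op.half_width, radius_px)
    a = float(np.sum(op.kernel_dog[disc]))  # DOG mass inside the spot
    b = float(np.sum(op.kernel_normalizer[disc]))  # normalizer mass inside
    s = np.linspace(0.0, 1.0, LOOKUP_GRID_POINTS)
    responses = (s - 0.5) * a / (0.5 + (s - 0.5) * b)
    if np.any(np.diff(responses) <= 0):
        raise RuntimeError("spot responses are not monotone in spot luminance")
    if definition == "weber":
        contrasts = 100.0 * (s - 0.5) / 0.5
    else:
        contrasts = 100.0 * (s - 0.5) / (s + 0.5)
    return LookupTable(responses, contrasts)


def apply_operator(image: LuminanceImage, op: ContrastOperator) -> ContrastMap:
    """Apply the normalized DOG; returns the raw contrast map.

    Margins of half the kernel side are cropped, so every retained pixel's
    response uses only in-image luminance.  Raises if the normalizer
    response is zero anywhere in the retained region.
    """
    lum = image.values
    if min(lum.shape) < op.kernel_center.shape[0]:
        raise ValueError(
            f"image {lum.shape} smaller than the operator kernel "
            f"{op.kernel_center.shape}; nothing would survive the crop"
        )
    num = fftconvolve(lum, op.kernel_dog, mode="valid")
    den = fftconvolve(lum, op.kernel_normalizer, mode="valid")
    if np.any(den <= 0):
        raise ZeroDivisionError(
            "normalizer response is zero under some retained pixel; "
            "luminance must be positive under every normalizer footprint"
        )
    raw = num / den
    return ContrastMap(raw, "raw", image.pixel_size, meta={"spec": vars(op.spec)})


def to_equivalent_contrast(raw_map: ContrastMap, lut: LookupTable, definition: str = "weber") -> ContrastMap:
    """Convert raw responses to equivalent percent contrast.

    Linear interpolation between table nodes; responses outside the table
    range are clamped to the end contrasts (+/-100% for Weber) and counted
    in ``clamped_fraction``.
    """
    raw = raw_map.values
    out_of_range = (raw < lut.responses[0]) | (raw > lut.responses[-1])
    values = np.interp(raw, lut.responses, lut.contrasts)
    return ContrastMap(
        values,
        definition,
        raw_map.pixel_size,
        clamped_fraction=float(np.mean(out_of_range)),
        meta=dict(raw_map.meta),
    )


def weber_lowpass_contrast(image: LuminanceImage, sigma: float) -> ContrastMap:
    """Single-parameter alternative contrast: pixel Weber vs low-pass mean.

    Each pixel's contrast is ``(L - b) / b * 100`` where ``b`` is the local
    average from a unit-sum Gaussian of standard deviation ``sigma``
    (arcmin).  Margins of half the kernel side are cropped.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    s_px = sigma / image.pixel_size
    half_width = int(np.ceil(KERNEL_EXTENT_SIGMAS * s_px))
    k1 = gaussian_kernel_1d(s_px, half_width)
    kernel = np.outer(k1, k1)
    if min(image.shape) < kernel.shape[0]:
        raise ValueError("image smaller than the low-pass kernel")
    local = fftconvolve(image.values, kernel, mode="valid")
    if np.any(local <= 0):
        raise ZeroDivisionError("local average luminance is zero under some pixel")
    center = image.values[half_width:-half_width, half_width:-half_width]
    values = 100.0 * (center - local) / local
    return ContrastMap(values, "weber", image.pixel_size, meta={"lowpass_sigma": sigma})


def split_bright_dark(cmap: ContrastMap) -> tuple[ContrastMap, ContrastMap]:
    """Split a contrast map into bright (>= 0) and dark (<= 0) components.

    The two components sum back to the input exactly; the suppressed
    polarity is set to zero in each.
    """
    bright = np.where(cmap.values > 0, cmap.values, 0.0)
    dark = np.where(cmap.values < 0, cmap.values, 0.0)
    mk = lambda v, pol: ContrastMap(
        v, cmap.definition, cmap.pixel_size, cmap.clamped_fraction,
        meta={**cmap.meta, "polarity": pol},
    )
    return mk(bright, "bright"), mk(dark, "dark")
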