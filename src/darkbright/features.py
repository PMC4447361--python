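"""Per-polarity feature distributions and dark/bright ratio curves.

Four feature axes are supported: equivalent contrast (overlapping-bin
histograms of the nonzero pixels of a contrast map), spatial frequency and
orientation (ring and wedge means over the Hanning-windowed Fourier
amplitude spectrum), and relative depth (contrast-amplitude-weighted
histograms of local dioptric depth differences).  Distributions for a
bright/dark pair are normalized *jointly* -- the total mass across both
polarities integrates to one -- so the global dark/bright imbalance is
preserved, and ratio curves exclude bins whose probability density falls
below 1e-5 in either polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .contrast import KERNEL_EXTENT_SIGMAS, ContrastMap, ContrastOperator, apply_operator, gaussian_kernel_1d, to_equivalent_contrast
from .io import DistanceMap, LuminanceImage

__all__ = [
    "FeatureDistribution",
    "RatioCurve",
    "contrast_distribution",
    "contrast_distributions",
    "fourier_distributions",
    "ensemble_fourier_distributions",
    "dark_bright_ratio",
    "relative_depth_distribution",
    "ensemble_relative_depth",
    "normalize_pair",
    "overlapping_histogram",
    "radial_amplitude_slope",
]

#: Contrast histogram geometry (percent contrast).
CONTRAST_BIN_WIDTH = 5.4
CONTRAST_BIN_STEP = 2.7
#: Relative-depth histogram geometry (diopters).
DEPTH_BIN_WIDTH = 1.6e-3
DEPTH_BIN_STEP = 7.9e-4
#: Ratio-curve exclusion threshold on probability density.
DENSITY_EXCLUSION = 1e-5
#: Number of logarithmic spatial-frequency rings.
N_FREQ_RINGS = 37
#: Orientation wedge geometry (degrees).
WEDGE_WIDTH = 10.0
WEDGE_STEP = 5.0
#: Gaussian for local-average distance (arcmin).
DEPTH_SMOOTHING_SIGMA = 30.0


@dataclass
class FeatureDistribution:
    """A binned amplitude/probability distribution over one feature axis."""

    feature: str  # contrast | spatial_frequency | orientation | relative_depth
    bin_centers: np.ndarray
    amplitude: np.ndarray  # raw summed amplitude or count per bin
    bin_step: float
    polarity: str = "all"  # bright | dark | all
    units: str = ""
    density: np.ndarray | None = None  # set by joint/single normalization
    normalization: str = "none"  # none | single | joint
    meta: dict = dataclass_field(default_factory=dict)

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if np.any(self.amplitude < -1e-12):
            raise ValueError("distribution amplitudes must be nonnegative")


@dataclass
class RatioCurve:
    """Per-bin dark/bright ratio with the low-density bins excluded."""

    bin_centers: np.ndarray
    ratio: np.ndarray
    excluded_mask: np.ndarray
    feature: str = ""
    units: str = ""


def overlapping_histogram(
    values: np.ndarray,
    centers: np.ndarray,
    width: float,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of ``weights`` (or counts) falling in ``[c - w/2, c + w/2)``.

    Bins may overlap; with a step of half the width each sample lands in
    two bins, which is the histogram smoothing used throughout.
    """
    values = np.asarray(values, dtype=float).ravel()
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    if weights is None:
        cum = np.arange(values.size + 1, dtype=float)
    else:
        w = np.asarray(weights, dtype=float).ravel()[order]
        cum = np.concatenate(([0.0], np.cumsum(w)))
    lo = np.searchsorted(sorted_vals, centers - width / 2, side="left")
    hi = np.searchsorted(sorted_vals, centers + width / 2, side="left")
    return cum[hi] - cum[lo]


def _bin_centers_covering(lo: float, hi: float, step: float) -> np.ndarray:
    """Bin centers at integer multiples of ``step`` spanning [lo, hi]."""
    k0 = int(np.floor(lo / step)) - 1
    k1 = int(np.ceil(hi / step)) + 1
    return np.arange(k0, k1 + 1) * step


def contrast_distribution(
    maps: Sequence[ContrastMap] | ContrastMap,
    polarity: str = "all",
    *,
    bin_width: float = CONTRAST_BIN_WIDTH,
    bin_step: float = CONTRAST_BIN_STEP,
) -> FeatureDistribution:
    """Smoothed histogram of equivalent contrasts over an ensemble of maps.

    Uses overlapping bins (width 5.4%, step 2.7%); pixels with contrast
    exactly zero are excluded.  ``polarity`` selects the positive pixels
    (``"bright"``), negative pixels (``"dark"``) or all nonzero pixels.
    The histogram is over contrast *magnitude*, so a bright and a dark
    distribution are directly comparable bin by bin (the dark/bright ratio
    at a contrast level compares dark at ``-c`` with bright at ``+c``).
    Counts are aggregated over all maps before any normalization.
    """
    if isinstance(maps, ContrastMap):
        maps = [maps]
    if not maps:
        raise ValueError("need at least one contrast map")
    if len({m.definition for m in maps}) != 1:
        raise ValueError("all maps must share one contrast definition")
    vals = np.concatenate([m.values.ravel() for m in maps])
    vals = vals[vals != 0.0]
    if polarity == "bright":
        vals = vals[vals > 0]
    elif polarity == "dark":
        vals = -vals[vals < 0]
    elif polarity == "all":
        vals = np.abs(vals)
    else:
        raise ValueError("polarity must be bright, dark or all")
    centers = _bin_centers_covering(0.0, max(100.0, vals.max() if vals.size else 100.0), bin_step)
    centers = centers[centers >= 0.0]
    counts = overlapping_histogram(vals, centers, bin_width)
    return FeatureDistribution(
        "contrast", centers, counts, bin_step, polarity=polarity, units="% contrast"
    )


def contrast_distributions(
    maps: Sequence[ContrastMap],
) -> tuple[FeatureDistribution, FeatureDistribution]:
    """Jointly normalized (bright, dark) contrast distributions."""
    bright = contrast_distribution(maps, "bright")
    dark = contrast_distribution(maps, "dark")
    normalize_pair(bright, dark)
    return bright, dark


def _align_pair(a: FeatureDistribution, b: FeatureDistribution) -> None:
    """Zero-pad two distributions onto the union of their bin grids.

    Needed when one polarity reaches further along the axis (e.g. bright
    low-pass Weber contrasts are unbounded above while dark stops at 100).
    The grids must share the step and the first center.
    """
    if a.bin_centers.size == b.bin_centers.size:
        return
    if a.bin_step != b.bin_step or a.bin_centers[0] != b.bin_centers[0]:
        raise ValueError("distributions on incompatible bin grids")
    short, long_ = (a, b) if a.bin_centers.size < b.bin_centers.size else (b, a)
    pad = long_.bin_centers.size - short.bin_centers.size
    short.bin_centers = long_.bin_centers.copy()
    short.amplitude = np.pad(short.amplitude, (0, pad))
    if short.density is not None:
        short.density = np.pad(short.density, (0, pad))


def normalize_pair(a: FeatureDistribution, b: FeatureDistribution) -> None:
    """Normalize two polarities to a joint probability density.

    After the call ``(sum(a.density) + sum(b.density)) * bin_step == 1``,
    preserving the global imbalance between the polarities.
    """
    _align_pair(a, b)
    total = (a.amplitude.sum() + b.amplitude.sum()) * a.bin_step
    if total <= 0:
        raise ValueError("cannot normalize empty distributions")
    for d in (a, b):
        d.density = d.amplitude / total
        d.normalization = "joint"


def _hanning_window(shape: tuple[int, int]) -> np.ndarray:
    """Circularly symmetric Hanning taper of radius min(shape)/2."""
    ny, nx = shape
    y = np.arange(ny) - (ny - 1) / 2
    x = np.arange(nx) - (nx - 1) / 2
    r = np.hypot(y[:, None], x[None, :])
    radius = min(ny, nx) / 2
    w = 0.5 * (1 + np.cos(np.pi * np.minimum(r / radius, 1.0)))
    return w


def _wedge_weights(theta: np.ndarray, center: float, half_width: float, ramp: np.ndarray) -> np.ndarray:
    """Anti-aliased wedge membership: trapezoid in orientation angle.

    ``theta`` in degrees mod 180; the linear ramp has per-pixel width
    ``ramp`` (one frequency pixel of arc), capped at the wedge width so
    adjacent wedges stay complementary.
    """
    d = np.abs((theta - center + 90.0) % 180.0 - 90.0)
    ramp = np.minimum(ramp, 2 * half_width)
    return np.clip((half_width + ramp / 2 - d) / ramp, 0.0, 1.0)


def _band_weights(f: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    """Anti-aliased radial band membership: trapezoid in frequency."""
    inner = np.clip((f - (lo - ramp / 2)) / ramp, 0.0, 1.0)
    outer = np.clip(((hi + ramp / 2) - f) / ramp, 0.0, 1.0)
    return inner * outer


def fourier_distributions(
    arr: np.ndarray | ContrastMap | LuminanceImage,
    pixel_size: float | None = None,
    *,
    n_rings: int = N_FREQ_RINGS,
) -> tuple[FeatureDistribution, FeatureDistribution, float]:
    """Spatial-frequency and orientation amplitude distributions of one map.

    The map is multiplied by a circularly symmetric Hanning window and its
    Fourier amplitude spectrum (normalized per pixel, so the zero-frequency
    amplitude equals the windowed map's absolute mean) is analyzed between
    4 cycles per image and the highest frequency present at all
    orientations (the axis Nyquist).  Spatial frequency is the mean
    amplitude over ``n_rings`` logarithmically spaced, anti-aliased ring
    masks (cycles/degree); orientation is the mean amplitude over 10
    degree wide anti-aliased wedges in steps of 5 degrees (0/180 =
    horizontal, 90 = vertical, conjugate half-planes combined).  The DC
    amplitude is returned separately.
    """
    if isinstance(arr, (ContrastMap, LuminanceImage)):
        if pixel_size is None:
            pixel_size = arr.pixel_size
        arr = arr.values
    if pixel_size is None:
        raise ValueError("pixel_size (arcmin) is required for a bare array")
    arr = np.asarray(arr, dtype=float)
    ny, nx = arr.shape
    n_min = min(ny, nx)
    if n_min < 16:
        raise ValueError("image too small for the 4 cycles/image low cutoff")
    px_deg = pixel_size / 60.0
    spectrum = np.abs(np.fft.fftshift(np.fft.fft2(arr * _hanning_window(arr.shape)))) / (ny * nx)
    fy = np.fft.fftshift(np.fft.fftfreq(ny)) / px_deg
    fx = np.fft.fftshift(np.fft.fftfreq(nx)) / px_deg
    f = np.hypot(fy[:, None], fx[None, :])  # cycles/degree
    theta = np.degrees(np.arctan2(fy[:, None], fx[None, :])) % 180.0

    dc_index = (ny // 2, nx // 2)
    dc_amplitude = float(spectrum[dc_index])

    f_pixel = 1.0 / (n_min * px_deg)  # one frequency pixel, cpd
    f_lo = 4.0 * f_pixel  # 4 cycles per image
    f_hi = 0.5 / px_deg  # axis Nyquist: present at all orientations

    # --- spatial frequency: log-spaced rings with geometric edges ---
    log_centers = np.linspace(np.log10(f_lo), np.log10(f_hi), n_rings)
    centers = 10.0**log_centers
    half_ratio = 10.0 ** (np.diff(log_centers)[0] / 2)
    ring_amp = np.empty(n_rings)
    for i, c in enumerate(centers):
        w = _band_weights(f, c / half_ratio, c * half_ratio, f_pixel)
        w[dc_index] = 0.0
        ring_amp[i] = np.average(spectrum, weights=w) if w.sum() > 0 else 0.0
    sf = FeatureDistribution(
        "spatial_frequency", centers, ring_amp, np.diff(log_centers)[0],
        units="cpd", meta={"log10_step": True, "f_lo": f_lo, "f_hi": f_hi},
    )

    # --- orientation: anti-aliased wedges over the annulus ---
    annulus = _band_weights(f, f_lo, f_hi, f_pixel)
    annulus[dc_index] = 0.0
    with np.errstate(divide="ignore"):
        ramp = np.degrees(np.where(f > 0, f_pixel / np.maximum(f, 1e-300), np.inf))
    ori_centers = np.arange(0.0, 180.0, WEDGE_STEP)
    ori_amp = np.empty(ori_centers.size)
    for i, c in enumerate(ori_centers):
        w = _wedge_weights(theta, c, WEDGE_WIDTH / 2, ramp) * annulus
        ori_amp[i] = np.average(spectrum, weights=w) if w.sum() > 0 else 0.0
    ori = FeatureDistribution(
        "orientation", ori_centers, ori_amp, WEDGE_STEP, units="deg"
    )
    return sf, ori, dc_amplitude


def ensemble_fourier_distributions(
    maps: Iterable[np.ndarray | ContrastMap],
    pixel_size: float | None = None,
    *,
    polarity: str = "all",
) -> tuple[FeatureDistribution, FeatureDistribution, float]:
    """Sum single-map Fourier distributions over an ensemble."""
    sf_total = ori_total = None
    dc_total = 0.0
    n = 0
    for m in maps:
        sf, ori, dc = fourier_distributions(m, pixel_size)
        if sf_total is None:
            sf_total, ori_total = sf, ori
        else:
            sf_total.amplitude = sf_total.amplitude + sf.amplitude
            ori_total.amplitude = ori_total.amplitude + ori.amplitude
        dc_total += dc
        n += 1
    if sf_total is None:
        raise ValueError("empty ensemble")
    for d in (sf_total, ori_total):
        d.polarity = polarity
        d.meta["n_images"] = n
    return sf_total, ori_total, dc_total


def dark_bright_ratio(
    dark: FeatureDistribution,
    bright: FeatureDistribution,
    dc_pair: tuple[float, float] | None = None,
    *,
    threshold: float = DENSITY_EXCLUSION,
) -> RatioCurve:
    """Per-bin ratio of dark to bright amplitude.

    Bins where either polarity's probability density falls below
    ``threshold`` are excluded.  For orientation distributions,
    ``dc_pair = (dc_dark, dc_bright)`` adds each polarity's separately
    computed DC amplitude back in uniformly before the ratio is taken
    (the Fourier analysis removed it).
    """
    _align_pair(dark, bright)
    if not np.allclose(dark.bin_centers, bright.bin_centers):
        raise ValueError("distributions must share bin centers")
    d_amp = dark.amplitude.astype(float).copy()
    b_amp = bright.amplitude.astype(float).copy()
    if dc_pair is not None:
        dc_dark, dc_bright = dc_pair
        d_amp += dc_dark
        b_amp += dc_bright
    if dark.density is None or bright.density is None:
        normalize_pair(dark, bright)
    excluded = (dark.density < threshold) | (bright.density < threshold)
    if np.all(excluded):
        raise ValueError("all bins excluded by the density threshold")
    ratio = np.full_like(d_amp, np.nan)
    keep = ~excluded
    ratio[keep] = d_amp[keep] / b_amp[keep]
    return RatioCurve(dark.bin_centers.copy(), ratio, excluded, dark.feature, dark.units)


def _masked_local_average(values: np.ndarray, mask: np.ndarray, sigma_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian local average using only valid samples under the filter."""
    half_width = int(np.ceil(KERNEL_EXTENT_SIGMAS * sigma_px))
    k1 = gaussian_kernel_1d(sigma_px, half_width)
    kernel = np.outer(k1, k1)
    weight = fftconvolve(mask.astype(float), kernel, mode="same")
    summed = fftconvolve(np.where(mask, values, 0.0), kernel, mode="same")
    ok = weight > 1e-12
    avg = np.full_like(summed, np.nan)
    avg[ok] = summed[ok] / weight[ok]
    return avg, ok


def _relative_depth_samples(
    image: LuminanceImage, dmap: DistanceMap, op: ContrastOperator
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (relative depth [D], equivalent Weber contrast [%]) samples.

    Relative depth is the local-average dioptric distance minus the pixel's
    dioptric distance, so farther-than-surround pixels are positive.  The
    local average distance comes from a 30 arcmin Gaussian over the valid
    distances only; pixels that are invalid or have no valid neighborhood
    are dropped.
    """
    if image.shape != dmap.shape:
        raise ValueError("image and distance map shapes must match")
    cmap = to_equivalent_contrast(apply_operator(image, op), op.lookup("weber"))
    avg_dist, ok = _masked_local_average(
        dmap.values, dmap.valid_mask, DEPTH_SMOOTHING_SIGMA / image.pixel_size
    )
    hw = op.half_width
    sl = (slice(hw, image.shape[0] - hw), slice(hw, image.shape[1] - hw))
    valid = dmap.valid_mask[sl] & ok[sl] & (avg_dist[sl] > 0)
    rel = 1.0 / avg_dist[sl][valid] - 1.0 / dmap.values[sl][valid]
    return rel, cmap.values[valid]


def _depth_pair_from_samples(
    rel: np.ndarray, contrast: np.ndarray
) -> tuple[FeatureDistribution, FeatureDistribution]:
    if rel.size == 0:
        raise ValueError("no valid depth samples")
    centers = _bin_centers_covering(rel.min(), rel.max(), DEPTH_BIN_STEP)
    out = []
    for pol, sel in (("dark", contrast < 0), ("bright", contrast > 0)):
        amp = overlapping_histogram(
            rel[sel], centers, DEPTH_BIN_WIDTH, weights=np.abs(contrast[sel])
        )
        out.append(
            FeatureDistribution(
                "relative_depth", centers, amp, DEPTH_BIN_STEP, polarity=pol, units="D"
            )
        )
    dark, bright = out
    normalize_pair(dark, bright)
    return dark, bright


def relative_depth_distribution(
    image: LuminanceImage, dmap: DistanceMap, op: ContrastOperator
) -> tuple[FeatureDistribution, FeatureDistribution]:
    """(dark, bright) contrast-amplitude distributions over relative depth.

    Amplitude per bin is the summed |equivalent contrast| of the pixels of
    that polarity whose relative depth falls in the bin (bins 1.6e-3 D
    wide in steps of 7.9e-4 D).
    """
    rel, con = _relative_depth_samples(image, dmap, op)
    return _depth_pair_from_samples(rel, con)


def ensemble_relative_depth(
    pairs: Sequence[tuple[LuminanceImage, DistanceMap]], op: ContrastOperator
) -> tuple[FeatureDistribution, FeatureDistribution]:
    """Aggregate the relative-depth distributions over image/map pairs."""
    rels, cons = [], []
    for image, dmap in pairs:
        r, c = _relative_depth_samples(image, dmap, op)
        rels.append(r)
        cons.append(c)
    return _depth_pair_from_samples(np.concatenate(rels), np.concatenate(cons))


def radial_amplitude_slope(
    arr: np.ndarray, f_lo: float, f_hi: float, n_rings: int = 20
) -> float:
    """Log-log slope of the radially averaged Fourier amplitude.

    Frequencies are in cycles/image (of the smaller dimension); the fit is
    over ``n_rings`` log-spaced rings between ``f_lo`` and ``f_hi``.  No
    taper is applied (intended for circularly stationary synthetic fields).
    """
    arr = np.asarray(arr, dtype=float)
    ny, nx = arr.shape
    spectrum = np.abs(np.fft.fftshift(np.fft.fft2(arr - arr.mean())))
    fy = np.fft.fftshift(np.fft.fftfreq(ny)) * min(ny, nx)
    fx = np.fft.fftshift(np.fft.fftfreq(nx)) * min(ny, nx)
    f = np.hypot(fy[:, None], fx[None, :])
    edges = np.geomspace(f_lo, f_hi, n_rings + 1)
    log_f, log_a = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (f >= lo) & (f < hi)
        if np.any(sel):
            log_f.append(np.log10(np.sqrt(lo * hi)))
            log_a.append(np.log10(spectrum[sel].mean()))
    slope = np.polyfit(log_f, log_a, 1)[0]
    return float(slope)
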