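"""Synthetic image and distance-map generators.

Five cumulative classes of noise images stand in for calibrated natural
image datasets:

1. Gaussian white noise (flat amplitude spectrum, random phase);
2. amplitude shaped to a 1/f^alpha fall-off (alpha = 1.3);
3. plus positively skewed intensities (field rescaled to [0, 1] and
   raised to the third power, then restored to its previous mean/variance);
4. plus a cardinal-orientation energy boost (raised-cosine amplitude bands
   around 0 and 90 degrees);
5. identical images, with distance maps negatively coupled to intensity
   (intensities standardized, scaled by 2.5 and subtracted from the
   distances; mean Pearson r targeted at -0.07).

Every class also carries a paired distance map: a 1/f^1.3-attenuated
Gaussian field scaled to a per-map depth range averaging 80 m around a
per-map random mean distance averaging 40 m.  Classes built from the same
seed share the identical underlying random fields, so differences between
classes are due only to the added structure.

Calibration spot and bar stimuli for the contrast lookup and the afferent
bar simulation are also generated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .contrast import ContrastOperator
from .io import DistanceMap, LuminanceImage

__all__ = [
    "NoiseSpec",
    "generate_noise",
    "generate_spot",
    "generate_bar",
    "generate_random_baselines",
]

#: Target mean intensity/distance Pearson correlation for class-5 coupling.
COUPLING_TARGET_R = -0.07
#: Printed coupling scale: standardized intensities times this are
#: subtracted from the distances.
COUPLING_SCALE = 2.5
#: Positive luminance floor after the nonnegativity shift, as a fraction
#: of the mean (the divisive contrast normalization needs L > 0).
LUMINANCE_FLOOR_FRACTION = 0.01
#: Smallest distance retained in synthetic maps (meters).
DISTANCE_FLOOR = 0.1


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one class of synthetic noise.

    Defaults are the ensemble conditions used throughout: 25 pairs of
    1024 x 1024 images at 1 arcmin/px, spectral exponent 1.3, cubic
    intensity skew, a x2 raised-cosine cardinal boost of 10 degree
    half-width, 40 m mean distance, 80 m mean depth range, and coupling
    scale 2.5 for class 5.
    """

    noise_class: int = 1
    n_images: int = 25
    size: tuple[int, int] = (1024, 1024)
    alpha: float = 1.3
    skew_exponent: float = 3.0
    orientation_boost: float = 2.0
    orientation_band_halfwidth: float = 10.0  # degrees
    depth_mean: float = 40.0  # meters
    depth_range: float = 80.0  # meters
    depth_coupling: float = COUPLING_SCALE
    pixel_size: float = 1.0  # arcmin
    seed: int = 0

    def __post_init__(self):
        if self.noise_class not in (1, 2, 3, 4, 5):
            raise ValueError("noise_class must be 1..5")
        if self.n_images <= 0:
            raise ValueError("n_images must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def _radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    """Radial frequency in cycles per (smaller) image dimension."""
    ny, nx = shape
    n_min = min(ny, nx)
    fy = np.fft.fftfreq(ny) * n_min
    fx = np.fft.fftfreq(nx) * n_min
    return np.hypot(fy[:, None], fx[None, :])


def _shape_spectrum(field: np.ndarray, alpha: float) -> np.ndarray:
    """Impose a 1/f^alpha amplitude envelope, leaving DC untouched."""
    f = _radial_frequency(field.shape)
    envelope = np.ones_like(f)
    nonzero = f > 0
    envelope[nonzero] = f[nonzero] ** (-alpha)
    shaped = np.fft.ifft2(np.fft.fft2(field) * envelope).real
    # preserve unit variance so later stages see a consistent scale
    return shaped / shaped.std()


def _skew_field(field: np.ndarray, exponent: float) -> np.ndarray:
    """Positively skew a signed field: rescale to [0, 1], raise to a power,
    then restore the original mean and variance."""
    lo, hi = field.min(), field.max()
    z = (field - lo) / (hi - lo)
    y = z**exponent
    return (y - y.mean()) / y.std() * field.std() + field.mean()


def _orientation_boost(
    field: np.ndarray, boost: float, halfwidth_deg: float
) -> np.ndarray:
    """Multiply Fourier amplitudes by a raised-cosine cardinal-band mask."""
    ny, nx = field.shape
    fy = np.fft.fftfreq(ny)
    fx = np.fft.fftfreq(nx)
    theta = np.degrees(np.arctan2(fy[:, None], fx[None, :])) % 180.0
    # angular distance to the nearest cardinal orientation (0/90/180)
    d = np.minimum(np.abs((theta + 45.0) % 90.0 - 45.0), 90.0)
    mask = np.where(
        d <= halfwidth_deg,
        1.0 + (boost - 1.0) * 0.5 * (1 + np.cos(np.pi * d / halfwidth_deg)),
        1.0,
    )
    mask[0, 0] = 1.0
    boosted = np.fft.ifft2(np.fft.fft2(field) * mask).real
    return boosted / boosted.std()


def _shift_nonnegative(field: np.ndarray) -> np.ndarray:
    """Add a constant so the minimum is a small positive luminance floor."""
    m, mu = field.min(), field.mean()
    c = (LUMINANCE_FLOOR_FRACTION * mu - m) / (1 - LUMINANCE_FLOOR_FRACTION)
    return field + c


def _distance_field(rng: np.random.Generator, spec: NoiseSpec) -> tuple[np.ndarray, float]:
    """A 1/f^alpha Gaussian distance map around a random mean distance.

    Returns the map and its pre-coupling standard deviation.  The field is
    scaled so its per-map range (max - min) equals ``depth_range``, and
    centered on a per-map mean drawn uniformly within +/-50% of
    ``depth_mean`` (so the ensemble mean distance is ``depth_mean``).
    """
    base = rng.standard_normal(spec.size)
    shaped = _shape_spectrum(base, spec.alpha)
    span = shaped.max() - shaped.min()
    scaled = shaped * (spec.depth_range / span)
    mean_dist = rng.uniform(0.5 * spec.depth_mean, 1.5 * spec.depth_mean)
    return scaled - scaled.mean() + mean_dist, float(scaled.std())


def _coupling_intensity_std(sigma_d: float, scale: float, target_r: float) -> float:
    """Standard deviation to which intensities are standardized before the
    scale-and-subtract coupling, chosen so the expected Pearson correlation
    between (independent) intensity and coupled distance equals
    ``target_r``:  r = -scale*sigma_z / sqrt(sigma_d^2 + scale^2 sigma_z^2).
    """
    r = abs(target_r)
    return r * sigma_d / (scale * np.sqrt(1.0 - r**2))


def generate_noise(spec: NoiseSpec) -> list[tuple[LuminanceImage, DistanceMap]]:
    """Generate ``n_images`` image/distance-map pairs of the given class.

    Deterministic for a given seed (NumPy ``default_rng`` with per-image
    seed sequences); class k and class k+1 at the same seed share the same
    underlying random fields.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_images)
    pairs = []
    for i, child in enumerate(children):
        img_seq, dist_seq = child.spawn(2)
        rng_img = np.random.default_rng(img_seq)
        rng_dist = np.random.default_rng(dist_seq)

        field = rng_img.standard_normal(spec.size)
        if spec.noise_class >= 2:
            field = _shape_spectrum(field, spec.alpha)
        if spec.noise_class >= 3:
            field = _skew_field(field, spec.skew_exponent)
        if spec.noise_class >= 4:
            field = _orientation_boost(
                field, spec.orientation_boost, spec.orientation_band_halfwidth
            )
        lum = _shift_nonnegative(field)

        dist, sigma_d = _distance_field(rng_dist, spec)
        if spec.noise_class >= 5:
            z0 = (lum - lum.mean()) / lum.std()
            # The distance noise is constructed orthogonal to the intensity
            # field, so the coupling below imposes exactly the intended
            # correlation instead of target-plus-sampling-noise (the two
            # 1/f fields have few effective degrees of freedom, so their
            # chance sample correlation is otherwise large).
            dist = dist - np.mean((dist - dist.mean()) * z0) * z0
            sigma_d = float(dist.std())
            sigma_z = _coupling_intensity_std(
                sigma_d, spec.depth_coupling, COUPLING_TARGET_R
            )
            dist = dist - spec.depth_coupling * sigma_z * z0
        dist = np.maximum(dist, DISTANCE_FLOOR)

        pairs.append(
            (
                LuminanceImage(
                    lum, pixel_size=spec.pixel_size,
                    source_id=f"noise-class{spec.noise_class}-{i:03d}",
                ),
                DistanceMap(dist, pixel_size=spec.pixel_size),
            )
        )
    return pairs


def generate_spot(
    op: ContrastOperator,
    spot_luminance: float,
    background: float = 0.5,
    field_size: int | None = None,
) -> LuminanceImage:
    """A uniform disc on a uniform background, for contrast calibration.

    The disc diameter equals the operator's positive-lobe FWHM and a pixel
    belongs to the disc if its center lies within it.  ``field_size``
    defaults to the smallest odd field whose central pixel survives the
    operator's crop; smaller fields raise.
    """
    if not 0.0 <= spot_luminance <= 1.0:
        raise ValueError("spot_luminance must be in [0, 1]")
    hw = op.half_width
    radius_px = 0.5 * op.fwhm_positive_lobe / op.pixel_size
    min_size = max(2 * hw + 1, int(np.ceil(2 * radius_px)) + 2 * hw)
    if field_size is None:
        field_size = min_size if min_size % 2 == 1 else min_size + 1
    if field_size < min_size:
        raise ValueError(
            f"field_size {field_size} too small for spot plus kernel margin ({min_size})"
        )
    x = np.arange(field_size) - (field_size - 1) / 2
    r = np.hypot(x[:, None], x[None, :])
    values = np.where(r <= radius_px, spot_luminance, background)
    return LuminanceImage(values, pixel_size=op.pixel_size, source_id="calibration-spot")


def generate_bar(
    polarity: str,
    contrast: float = 100.0,
    pixel_size: float = 1.0,
    background: float = 0.5,
) -> LuminanceImage:
    """A 10 x 30 arcmin bar centered on a 50 arcmin uniform square.

    The bar luminance is set so its Weber contrast against the square is
    ``+contrast`` (bright) or ``-contrast`` (dark) percent; dark bars above
    100% would need negative luminance and raise.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    if contrast < 0:
        raise ValueError("contrast must be nonnegative (polarity sets the sign)")
    w = contrast if polarity == "bright" else -contrast
    if w < -100.0:
        raise ValueError("dark bars beyond -100% Weber contrast are unphysical")
    side = round(50 / pixel_size)
    bar_w = round(10 / pixel_size)
    bar_h = round(30 / pixel_size)
    values = np.full((side, side), background)
    r0 = (side - bar_h) // 2
    c0 = (side - bar_w) // 2
    values[r0 : r0 + bar_h, c0 : c0 + bar_w] = background * (1 + w / 100.0)
    return LuminanceImage(values, pixel_size=pixel_size, source_id=f"{polarity}-bar-{contrast:g}%")


def generate_random_baselines(
    n: int, size: tuple[int, int] = (1024, 1024), seed: int = 0, *, pixel_size: float = 1.0
) -> tuple[list[LuminanceImage], list[DistanceMap]]:
    """Unstructured baselines: Gaussian white-noise luminance and
    independent random distances (for first-order reference distributions)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    children = np.random.SeedSequence(seed).spawn(n)
    images, dmaps = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        lum = _shift_nonnegative(rng.standard_normal(size))
        dist = np.maximum(rng.normal(40.0, 20.0, size), DISTANCE_FLOOR)
        images.append(
            LuminanceImage(lum, pixel_size=pixel_size, source_id=f"random-baseline-{i:03d}")
        )
        dmaps.append(DistanceMap(dist, pixel_size=pixel_size))
    return images, dmaps
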