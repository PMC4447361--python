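"""Retinal ganglion cell subpopulation model.

Eight subpopulations -- parvocellular (midget) and magnocellular (parasol)
pathways, foveal and peripheral locations, ON and OFF polarities -- each
combine a divisively normalized DOG receptive field with a static
contrast-response nonlinearity.  Receptive-field center sizes follow the
measured median geometry (arcmin):

======================  ======  ======
pathway / location        ON     OFF
======================  ======  ======
P foveal                  1.4     1.1
P peripheral              3.3     2.7
M foveal                  4.7     3.8
M peripheral              8.4     6.9
======================  ======  ======

The surround (and normalizer) standard deviation is six times the center;
the ON/OFF values are the collapsed size scaled by 110% and 90%.  The
nonlinearity is a cumulative Gaussian of equivalent Weber contrast,
``f(w') = (1 + erf((w' - mu)/(sigma sqrt(2)))) / 2`` with (mu, sigma) =
(37.5, 30) for ON and (60, 20) for OFF (the OFF branch sees ``-w'``),
normalized to 1 at the preferred 100% contrast; the ON response is then
halved to reflect its lower maximum rate.  P cells are weighted 9:1 over M
cells in all population summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.special import erf

from .contrast import ContrastOperator, DogSpec, apply_operator, make_operator, to_equivalent_contrast
from .features import FeatureDistribution, contrast_distribution, dark_bright_ratio, normalize_pair, overlapping_histogram, CONTRAST_BIN_STEP, CONTRAST_BIN_WIDTH, _bin_centers_covering
from .io import LuminanceImage
from .synthetic import generate_bar

__all__ = [
    "NonlinearitySpec",
    "RGCSubpopulation",
    "ResponseMap",
    "AfferentSummary",
    "ON_PARAMS",
    "OFF_PARAMS",
    "TABLE1_SIGMA_C",
    "build_subpopulations",
    "response_nonlinearity",
    "simulate_responses",
    "off_bias",
    "bar_afferent_ratio",
]

#: (midpoint %, spread %) of the cumulative-Gaussian contrast response.
ON_PARAMS = (37.5, 30.0)
OFF_PARAMS = (60.0, 20.0)
#: Surround std dev as a multiple of the center std dev.
SURROUND_FACTOR = 6.0
#: P cells are this many times more numerous than M cells.
PM_WEIGHT = 9.0
#: Center Gaussian standard deviations, arcmin (pathway, location) -> (ON, OFF).
TABLE1_SIGMA_C = {
    ("P", "foveal"): (1.4, 1.1),
    ("P", "peripheral"): (3.3, 2.7),
    ("M", "foveal"): (4.7, 3.8),
    ("M", "peripheral"): (8.4, 6.9),
}


@dataclass(frozen=True)
class NonlinearitySpec:
    """Cumulative-Gaussian contrast-response parameters for one polarity."""

    polarity: str  # "ON" | "OFF"
    mu_f: float
    sigma_f: float
    gain: float

    @classmethod
    def for_polarity(cls, polarity: str) -> "NonlinearitySpec":
        if polarity == "ON":
            return cls("ON", *ON_PARAMS, gain=0.5)
        if polarity == "OFF":
            return cls("OFF", *OFF_PARAMS, gain=1.0)
        raise ValueError("polarity must be 'ON' or 'OFF'")


def response_nonlinearity(w_prime, spec: NonlinearitySpec):
    """Expected RGC response (in [0, gain]) at equivalent Weber contrast.

    ``w_prime`` (percent) is clamped to [-100, 100]; the OFF branch
    negates it.  The cumulative Gaussian is normalized to 1 at the
    preferred-polarity 100% contrast and scaled by the polarity gain
    (1/2 for ON).
    """
    w = np.clip(np.asarray(w_prime, dtype=float), -100.0, 100.0)
    arg = w if spec.polarity == "ON" else -w

    def f(x):
        return 0.5 * (1.0 + erf((x - spec.mu_f) / (spec.sigma_f * np.sqrt(2.0))))

    return spec.gain * f(arg) / f(100.0)


@dataclass
class RGCSubpopulation:
    """One model cell class: receptive field plus response nonlinearity."""

    pathway: str  # "P" | "M"
    location: str  # "foveal" | "peripheral"
    polarity: str  # "ON" | "OFF"
    sigma_c: float  # arcmin
    operator: ContrastOperator
    nonlinearity: NonlinearitySpec

    @property
    def sigma_s(self) -> float:
        return self.operator.spec.sigma_s

    @property
    def name(self) -> str:
        return f"{self.pathway}-{self.location}-{self.polarity}"


def build_subpopulations(pixel_size: float = 1.0) -> list[RGCSubpopulation]:
    """Construct the eight model subpopulations.

    Each gets its own operator (surround and normalizer at six times the
    center, zero-sum, divisively normalized) discretized with 4x sub-pixel
    supersampling -- the smallest foveal P kernels are near one pixel at
    the default 1 arcmin/px grid -- and its own equivalent-Weber lookup
    built at its own positive-lobe FWHM.
    """
    subpops = []
    for (pathway, location), sigmas in TABLE1_SIGMA_C.items():
        for polarity, sigma_c in zip(("ON", "OFF"), sigmas):
            op = make_operator(
                DogSpec(sigma_c, SURROUND_FACTOR * sigma_c),
                pixel_size=pixel_size,
                oversample=4,
            )
            subpops.append(
                RGCSubpopulation(
                    pathway, location, polarity, sigma_c, op,
                    NonlinearitySpec.for_polarity(polarity),
                )
            )
    return subpops


@dataclass
class ResponseMap:
    """Per-pixel RGC responses with the driving equivalent contrast."""

    response: np.ndarray  # in [0, 1]
    w_prime: np.ndarray  # clamped equivalent Weber contrast, percent
    subpop: RGCSubpopulation
    pixel_size: float


def simulate_responses(image: LuminanceImage, subpop: RGCSubpopulation) -> ResponseMap:
    """Image -> raw DOG response -> equivalent Weber contrast -> response.

    Margins of half the receptive-field kernel are cropped by the contrast
    stage; equivalent contrasts are clamped to +/-100% before the
    nonlinearity.
    """
    cmap = to_equivalent_contrast(
        apply_operator(image, subpop.operator), subpop.operator.lookup("weber")
    )
    w_prime = np.clip(cmap.values, -100.0, 100.0)
    response = response_nonlinearity(w_prime, subpop.nonlinearity)
    return ResponseMap(response, w_prime, subpop, image.pixel_size)


def _subpop_weight(subpop: RGCSubpopulation, pm_weight: float) -> float:
    """9:1 P:M weighting with foveal and peripheral averaged equally."""
    return (pm_weight if subpop.pathway == "P" else 1.0) * 0.5


@dataclass
class AfferentSummary:
    """Summed ON/OFF afferent amplitudes and OFF-bias summaries."""

    totals: dict  # subpop name -> summed response amplitude
    off_bias_by_class: dict  # (pathway, location) -> OFF/ON ratio
    off_bias_overall: float  # P:M-weighted OFF/ON ratio
    pm_weight: float
    contrast_amplitude: dict = dataclass_field(default_factory=dict)
    contrast_off_bias: dict = dataclass_field(default_factory=dict)


def off_bias(
    images,
    subpops: list[RGCSubpopulation] | None = None,
    pm_weight: float = PM_WEIGHT,
    *,
    with_contrast_profile: bool = True,
) -> AfferentSummary:
    """Summed OFF/ON response amplitude over an image ensemble.

    Per (pathway, location) class, the OFF bias is the summed OFF response
    divided by the summed ON response over all images; the overall bias
    weights P classes ``pm_weight`` : 1 over M classes with foveal and
    peripheral averaged.  With ``with_contrast_profile`` the responses are
    also binned by the driving equivalent contrast -- ON responses
    aggregated only at positive contrasts, OFF only at negative -- giving
    the per-feature OFF-bias profile.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    if subpops is None:
        subpops = build_subpopulations(images[0].pixel_size)
    # responses binned by contrast magnitude, ON at positive contrasts and
    # OFF at negative, so the per-bin OFF/ON ratio compares equal |c|
    centers = _bin_centers_covering(0.0, 100.0, CONTRAST_BIN_STEP)
    centers = centers[centers >= 0.0]
    totals: dict[str, float] = {}
    amp_by_contrast: dict[str, np.ndarray] = {}
    for sp in subpops:
        total = 0.0
        amp = np.zeros(centers.size)
        for image in images:
            rmap = simulate_responses(image, sp)
            total += float(rmap.response.sum())
            if with_contrast_profile:
                sel = rmap.w_prime > 0 if sp.polarity == "ON" else rmap.w_prime < 0
                amp += overlapping_histogram(
                    np.abs(rmap.w_prime[sel]), centers, CONTRAST_BIN_WIDTH,
                    weights=rmap.response[sel],
                )
        totals[sp.name] = total
        amp_by_contrast[sp.name] = amp

    by_class = {}
    for pathway, location in TABLE1_SIGMA_C:
        on = totals[f"{pathway}-{location}-ON"]
        off = totals[f"{pathway}-{location}-OFF"]
        if on <= 0:
            raise ZeroDivisionError("zero total ON amplitude")
        by_class[(pathway, location)] = off / on

    w = {sp.name: _subpop_weight(sp, pm_weight) for sp in subpops}
    on_total = sum(w[n] * t for n, t in totals.items() if n.endswith("-ON"))
    off_total = sum(w[n] * t for n, t in totals.items() if n.endswith("-OFF"))
    if on_total <= 0:
        raise ZeroDivisionError("zero weighted ON amplitude")

    summary = AfferentSummary(totals, by_class, off_total / on_total, pm_weight)
    if with_contrast_profile:
        for name, amp in amp_by_contrast.items():
            summary.contrast_amplitude[name] = FeatureDistribution(
                "contrast", centers, amp, CONTRAST_BIN_STEP,
                polarity="bright" if name.endswith("-ON") else "dark",
                units="% contrast",
            )
        for key in TABLE1_SIGMA_C:
            on_d = summary.contrast_amplitude[f"{key[0]}-{key[1]}-ON"]
            off_d = summary.contrast_amplitude[f"{key[0]}-{key[1]}-OFF"]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(on_d.amplitude > 0, off_d.amplitude / np.maximum(on_d.amplitude, 1e-300), np.nan)
            summary.contrast_off_bias[key] = (centers.copy(), ratio)
    return summary


def _padded(image: LuminanceImage, margin: int, fill: float) -> LuminanceImage:
    values = np.pad(image.values, margin, constant_values=fill)
    return LuminanceImage(values, image.pixel_size, image.source_id + "+pad")


def bar_afferent_ratio(
    contrast: float = 100.0,
    subpops: list[RGCSubpopulation] | None = None,
    pm_weight: float = PM_WEIGHT,
    *,
    pixel_size: float = 1.0,
    background: float = 0.5,
) -> float:
    """Dark/bright ratio of total afferent activity for bar stimuli.

    A 10 x 30 arcmin bar of +/-``contrast``% Weber contrast on a 50 arcmin
    square is shown to all eight subpopulations (the square's background
    luminance is extended outward so the receptive fields are fully
    supported).  ON and OFF responses are summed over the whole square,
    weighted ``pm_weight`` : 1 for P : M with foveal and peripheral
    averaged, and the dark-bar total is divided by the bright-bar total.
    """
    if subpops is None:
        subpops = build_subpopulations(pixel_size)
    totals = {}
    for polarity in ("dark", "bright"):
        bar = generate_bar(polarity, contrast, pixel_size, background)
        side = bar.shape[0]
        total = 0.0
        for sp in subpops:
            hw = sp.operator.half_width
            rmap = simulate_responses(_padded(bar, hw, background), sp)
            assert rmap.response.shape == (side, side)
            total += _subpop_weight(sp, pm_weight) * float(rmap.response.sum())
        totals[polarity] = total
    return totals["dark"] / totals["bright"]
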