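# Methods

`darkbright` quantifies how bright (ON) and dark (OFF) visual features are
distributed in images, and how those distributions are reshaped by the
earliest stages of the primate visual pathway. This note records the model,
the numerical choices, and what the synthetic generators do and do not
emulate.

## Local contrast and bright/dark segmentation

A point in an image is "bright" or "dark" only relative to its local
surround. We operationalize this with a divisively normalized
difference-of-Gaussians (DOG) operator

    c(x, y) = (g_c * L − g_s * L) / (g_n * L),

where `g_c`, `g_s`, `g_n` are unit-sum 2-D Gaussians (center, surround,
normalizer) and `L` is linear luminance. The main-analysis geometry is
σ_c = 4 arcmin with surround/center ratio 2 and σ_n = σ_s; σ_c ∈ {2, 4, 8}
and ratios {1.5, 2, 4} are exposed as configuration for sensitivity sweeps,
as is a single-Gaussian low-pass Weber alternative. Because the numerator
is zero-sum and the denominator unit-sum, `c` is exactly invariant to
global luminance scaling; the divisive stage plays the role of local light
adaptation.

Numerical choices:

- Kernels are sampled on a square grid of half-width 4 σ_s pixels and each
  Gaussian is renormalized to exact unit sum, which makes the DOG exactly
  zero-sum on the discrete grid. An optional ×4 sub-pixel supersampling is
  used where σ_c approaches one pixel (the foveal P-cell receptive fields).
- Convolution is FFT-based; a margin of half the kernel side is cropped, so
  every retained pixel's response uses only in-image luminance and the
  boundary mode is irrelevant. FFT and direct spatial evaluation agree to
  1e-8 relative in the tests.
- The normalizer response must be strictly positive under every retained
  pixel; we raise rather than epsilon-patch, because a silent epsilon would
  distort statistics exactly where luminance is low.

Raw responses are converted to *equivalent contrast*: the Weber
(`(s−b)/b`) or Michelson (`(s−b)/(s+b)`) contrast of a uniform calibration
spot that would evoke the same center-pixel response. Spots have the
diameter of the DOG positive lobe at half maximum (FWHM, found by root
solving the continuous radial profile), luminances on a 1001-point grid in
[0, 1] against a 0.5 background, and are rasterized by pixel-center
membership. The response curve is evaluated in closed form from two
kernel/disc inner products, which is identical to filtering each spot
image; the lookup is inverted by linear interpolation and clamped to
±100%, with the clamped fraction recorded. Because a bright spot raises
the normalizer while a dark spot lowers it, equal-|Weber| spots do *not*
produce equal-magnitude responses — an asymmetry of the contrast
definition itself that propagates into the far tails of the measured
distributions. The round-trip error on calibration spots is below 0.5
contrast points across ±100%.

A map is segmented by sign: bright = positive contrasts, dark = negative,
with the complementary pixels zeroed; the two components always sum back
to the input exactly.

## Feature distributions and dark/bright ratios

- **Contrast**: overlapping-bin histograms (width 5.4%, step 2.7%) of the
  nonzero pixels. The 50% overlap *is* the smoothing; no further kernel is
  applied. Both polarities are binned by contrast magnitude so the
  dark/bright ratio at a level compares dark at −c with bright at +c.
- **Spatial frequency and orientation**: each map is tapered with a
  circularly symmetric Hanning window; the per-pixel-normalized Fourier
  amplitude spectrum is analyzed between 4 cycles/image and the axis
  Nyquist (the highest frequency present at all orientations). Spatial
  frequency uses 37 ring masks with centers equally spaced in log10
  frequency and edges at geometric midpoints; orientation uses 10°-wide
  wedges in 5° steps, with 0°/180° the horizontal frequency axis and
  conjugate half-planes combined. Both mask families are anti-aliased with
  a linear ramp one frequency pixel wide (capped at the mask width so that
  adjacent masks stay complementary: 36 non-overlapping 5° sectors tile
  the annulus to 1e-9).
- **DC handling**: windowing/FFT analysis removes each polarity's overall
  mean amplitude; it is returned separately and added back uniformly to
  the per-wedge amplitudes before the orientation ratio is formed (for
  spatial frequency it is not re-added). This is the simplest construction
  consistent with treating the overall dark/bright amplitude difference
  separately from its angular distribution.
- **Relative depth**: the local average distance is a 30 arcmin Gaussian
  over valid distances only (mask-normalized convolution, so image edges
  and missing values are handled without bias); relative depth is the
  local-average dioptric distance minus the pixel's dioptric distance
  (farther than surround ⇒ positive). Per polarity, the summed |equivalent
  contrast| is histogrammed in overlapping bins 1.6e-3 D wide in steps of
  7.9e-4 D. Any plotting clip to the central mass is presentation-only.
- **Normalization and ratios**: a bright/dark pair is normalized jointly —
  total mass across both polarities integrates to one — so global
  imbalance is preserved. Ratio curves divide summed amplitudes bin by bin
  and exclude bins whose probability density is below 1e-5 in either
  polarity. Distributions are aggregated over an ensemble before
  normalization and are invariant to image order.

## Synthetic noise classes

Five cumulative classes, each defaulting to 25 pairs of 1024² images at
1 arcmin/px, stand in for calibrated natural-image datasets:

1. Gaussian white noise;
2. amplitude spectrum shaped to 1/f^1.3 (multiply the FFT by f^−α with DC
   untouched; random phases come from the white field);
3. positive luminance skew: the field is rescaled to [0, 1], cubed, and
   affinely restored to its previous mean and variance (an odd power on a
   signed field would not skew it);
4. cardinal orientation boost: Fourier amplitudes multiplied by a
   raised-cosine band (default ×2, half-width 10°) around 0° and 90°. The
   boost magnitude is not dictated by any measurement; ×2 produces a
   clearly visible cardinal bias without dominating the spectrum and is
   exposed as configuration;
5. same images, with distance maps negatively coupled to intensity.

All luminance fields are shifted so the minimum is 1% of the mean (the
divisive contrast stage needs positive luminance). Distance maps for every
class are 1/f^1.3-shaped Gaussian fields scaled so the per-map range
(max − min) is 80 m — the literal reading of a "mean depth range" — and
centered on a per-map mean drawn uniformly in [20, 60] m (ensemble mean
40 m), floored at 0.1 m. Same seed ⇒ bit-identical output (NumPy
`default_rng` with spawned per-image seed sequences), and classes built
from one seed share the same underlying fields, so class contrasts isolate
the added structure.

For class 5, standardized intensities are scaled by 2.5 and subtracted
from the distances. The standardization target is derived analytically so
the expected Pearson correlation between intensity and distance is −0.07:
σ_z = |r| σ_d / (2.5 √(1−r²)). Two independent 1/f^1.3 fields at 1024²
have so few effective degrees of freedom that their chance sample
correlation has a standard deviation near 0.22; the generator therefore
first removes the sample projection of the distance noise onto the
intensity field, realizing at sample level the independence the
construction assumes. The achieved per-map correlation is −0.070 ± 0.001
rather than −0.07 ± 0.2.

The generators emulate amplitude-spectrum statistics only. They contain no
phase structure — no object boundaries, occlusions, or shadows — so
passing tests on them demonstrate that the measured asymmetries follow
from global first-order statistics plus the contrast normalization, not
that any specific natural-image number is reproduced. Headline values that
depend on particular calibrated photograph collections are dataset-
dependent and are only computed when a user supplies such data.

## Retinal ganglion cell model

Eight subpopulations (P/M × foveal/peripheral × ON/OFF) each combine a DOG
receptive field (center σ from the table in `darkbright.rgc`, surround and
normalizer at 6× center, ON sizes 110% and OFF 90% of the collapsed
median) with a static contrast-response nonlinearity: a cumulative
Gaussian of equivalent Weber contrast with (μ, σ) = (37.5, 30)% for ON and
(60, 20)% for OFF (argument negated), normalized to 1 at the preferred
100% contrast, the ON branch then halved. This reproduces the reference
worked values ON(+25%) = 0.17, OFF(−25%) = 0.04, ON(−25%) = 0.01.
Equivalent contrasts are clamped to ±100% before the nonlinearity; each
subpopulation calibrates its own lookup at its own FWHM. Luminance–
response interactions are not modeled; neither are retinotopic mosaics,
temporal dynamics, or spiking noise.

Afferent summaries weight P cells 9:1 over M cells with foveal and
peripheral locations averaged equally. The OFF bias is the summed OFF
response divided by the summed ON response, overall and per feature bin
(ON aggregated at positive contrasts, OFF at negative). For the bar
stimulus demonstration (10 × 30 arcmin bar at ±100% Weber on a 50 arcmin
square), responses are pooled over the whole square — the more operational
of the two plausible pooling readings; the pooling region is configurable
— giving a dark/bright afferent ratio of 1.94 at the defaults. The ratio
depends on bar size, pooling region and eccentricity mix, so the
meaningful claim is its magnitude (clearly above 1.5), not its third
decimal.

## Population model

A family of Gaussian tuning curves `h_j(s) = exp(−(s−μ_j)²/2σ²)` with
uniform spacing and common width, scaled by a maximum rate `R`, has Fisher
information `F(s) = Σ_j r_j′(s)²/r_j(s)` — evaluated analytically, linear
in `R`, and flat in `s` deep inside the tiled region (coefficient of
variation < 1e-6 five tuning widths inside the ends at spacing σ/10). The
discrimination-threshold lower bound is taken as `δ(s) = Δ/√F(s)`; this is
the only form under which the bright/dark threshold ratio equals
`√(F_d/F_b) = √(R_d/R_b)`, consistent with the stated 40% advantage at a
2:1 rate ratio. Δ defaults to 1 and cancels in every reported ratio.
Demo defaults: 25 neurons, spacing = σ, dark maximum rate 25 spikes/s,
rate ratio 2, evaluation ≥ 3σ inside the outermost preferred values.
Poisson/correlated decoding and non-Gaussian tuning are out of scope (the
construction is explicitly not a model of contrast encoding).

## Pipeline, determinism and problem sizes

`run_pipeline` sequences input → contrast → features → (optional) RGC with
a declarative config, writes CSV distributions/ratio curves plus a JSON
manifest of every parameter actually used, and is byte-deterministic for a
given config and seed. Natural-image runs are labeled dataset-dependent in
the manifest.

The test suite runs the stochastic checks at reduced ensemble sizes chosen
so each property is far from its decision boundary while the whole suite
stays fast: white-noise symmetry at 10 × 512², skewed-noise biases at
8 × 512², spectral slopes at 5 × 1024², coupling at 25 × 1024². The
acceptance script recomputes the six headline quantities from scratch at
these sizes in under a minute.

## Known limitations

- Orientation convention is the Fourier-domain angle (0° = horizontal
  frequency axis); users wanting "edge orientation" should rotate by 90°.
  The convention is recorded in output metadata.
- The Michelson lookup spans −100% to +33⅓% by construction (spot
  luminance ≤ 1 against background 0.5); Weber spans the full ±100%.
- Calibration-spot rasterization uses pixel-center membership without
  anti-aliasing; the calibration is self-consistent because the same rule
  is used throughout, but absolute OFF-bias levels are known to be
  sensitive to spot geometry while the per-feature patterns are robust.
- Whether the DC term should be re-added per wedge or as one offset to the
  summed orientation distribution is ambiguous; the uniform per-wedge
  offset is used.
- The low-luminance floor (1% of mean) and distance floor (0.1 m) are
  arbitrary small positive constants; results are insensitive to them at
  the default ensemble conditions.
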