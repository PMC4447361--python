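# darkbright

Dark/bright asymmetries in image statistics and their transformation by
the early visual pathways.

Natural scenes do not treat brights and darks symmetrically: dark features
carry more contrast energy, dominate low spatial frequencies, and tend to
lie at farther relative depths. The retina then processes the two
polarities through separate ON and OFF channels whose receptive-field
sizes and contrast-response nonlinearities also differ. `darkbright` is a
library and CLI for computational neuroscientists who want to measure
these second-order statistics and trace them through a model of the
retinal output:

- **contrast** — divisively normalized difference-of-Gaussians (DOG)
  operators, `c = (g_c*L − g_s*L)/(g_n*L)`, calibrated to equivalent
  Weber/Michelson contrast with spot stimuli, and bright/dark
  segmentation by sign;
- **features** — per-polarity distributions of contrast (overlapping
  5.4%-wide bins), spatial frequency and orientation (log ring and
  anti-aliased wedge means over Hanning-windowed amplitude spectra), and
  relative depth (diopters against the 30-arcmin local average), with
  jointly normalized densities and dark/bright ratio curves;
- **synthetic** — five cumulative noise classes (white → 1/f^1.3 →
  positively skewed → cardinally oriented → intensity/depth coupled, mean
  r = −0.07) with paired distance maps, plus calibration spots and bar
  stimuli;
- **rgc** — the eight retinal ganglion cell subpopulations (P/M ×
  foveal/peripheral × ON/OFF) with cumulative-Gaussian contrast-response
  functions `k(w') = ½·f(w'; 37.5, 30)` for ON and `f(−w'; 60, 20)` for
  OFF (each `f` normalized to 1 at the preferred 100% contrast), and
  OFF/ON afferent summaries at 9:1 P:M weighting;
- **population** — Gaussian-tuning complex-cell populations, Fisher
  information `F(s) = Σ_j r_j′(s)²/r_j(s)`, threshold bounds
  `δ = Δ/√F`, and the dark advantage `δ_b/δ_d = √(R_d/R_b)`.

## Worked example

```python
import numpy as np
from darkbright.contrast import DogSpec, make_operator, apply_operator, to_equivalent_contrast
from darkbright.features import contrast_distribution, dark_bright_ratio, normalize_pair
from darkbright.synthetic import NoiseSpec, generate_noise
from darkbright.rgc import NonlinearitySpec, response_nonlinearity, bar_afferent_ratio

# skewed 1/f^1.3 noise, segmented with the main-analysis operator
op = make_operator(DogSpec(sigma_c=4.0, sigma_s=8.0))
pairs = generate_noise(NoiseSpec(noise_class=3, n_images=8, size=(512, 512), seed=3))
maps = [to_equivalent_contrast(apply_operator(im, op), op.lookup_weber) for im, _ in pairs]

bright = contrast_distribution(maps, "bright")
dark = contrast_distribution(maps, "dark")
normalize_pair(bright, dark)
curve = dark_bright_ratio(dark, bright)
keep = ~curve.excluded_mask
lo = keep & (curve.bin_centers < 10)
hi = keep & (curve.bin_centers >= 30) & (curve.bin_centers <= 80)
print(f"dark/bright ratio: {np.nanmean(curve.ratio[lo]):.2f} at low contrast, "
      f"{np.nanmean(curve.ratio[hi]):.2f} at high contrast")

on = NonlinearitySpec.for_polarity("ON")
off = NonlinearitySpec.for_polarity("OFF")
print(f"RGC response at +25% (ON): {response_nonlinearity(25.0, on):.2f}, "
      f"at -25% (OFF): {response_nonlinearity(-25.0, off):.2f}")
print(f"bar afferent dark/bright ratio: {bar_afferent_ratio(100.0):.2f}")
```

prints

```
dark/bright ratio: 1.03 at low contrast, 1.52 at high contrast
RGC response at +25% (ON): 0.17, at -25% (OFF): 0.04
bar afferent dark/bright ratio: 1.94
```

Low-contrast features are nearly polarity-balanced while high contrasts
are biased dark (the skewed luminance histogram plus divisive
normalization produce this without any object or shadow geometry); the
ON/OFF nonlinearities map ±25% contrast to asymmetric responses; and a
dark bar drives about twice the total afferent signal of an equal-contrast
bright bar.

The CLI exposes the same machinery:

```bash
darkbright analyze --noise-class 5 --n 25 --size 1024 --seed 1 --with-rgc --out run/
darkbright make-noise --class 2 --n 25 --size 1024 --seed 1 --out noise/
darkbright bar-demo --contrast 100
darkbright population-demo --rate-ratio 2 --n-neurons 25
darkbright reproduce --which fig7 --out figures/
```

## Layout

```
src/darkbright/
  io.py          rasters (IML/TIFF/NPY/text), luminance and distance types
  contrast.py    DOG operators, spot calibration, bright/dark splitting
  features.py    distributions and ratio curves over the four feature axes
  synthetic.py   noise classes, spots, bars, random baselines
  rgc.py         the eight RGC subpopulations and afferent summaries
  population.py  Fisher information and discrimination bounds
  pipeline.py    declarative end-to-end runs and figure reproduction
  cli.py         the `darkbright` command
docs/methods.md  model details, numerical choices, limitations
```
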