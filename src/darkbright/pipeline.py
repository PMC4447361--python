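"""End-to-end analysis runs: images -> contrast -> features -> RGC.

A :class:`RunConfig` names the input source (a directory of supported
rasters or a synthetic :class:`~darkbright.synthetic.NoiseSpec`), the
contrast operator, and the summaries to compute.  :func:`run_pipeline`
writes per-feature distribution and ratio CSVs plus a JSON manifest
capturing every parameter actually used; identical config and seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contrast import (
    ContrastMap,
    DogSpec,
    apply_operator,
    make_operator,
    split_bright_dark,
    to_equivalent_contrast,
    weber_lowpass_contrast,
)
from .features import (
    FeatureDistribution,
    RatioCurve,
    contrast_distribution,
    dark_bright_ratio,
    ensemble_fourier_distributions,
    ensemble_relative_depth,
    normalize_pair,
)
from .io import LuminanceImage, read_raster
from .synthetic import NoiseSpec, generate_noise

logger = logging.getLogger("darkbright")

__all__ = ["RunConfig", "run_pipeline", "reproduce_figures"]

RASTER_SUFFIXES = (".iml", ".tif", ".tiff", ".npy", ".txt", ".csv")


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    out_dir: str = "darkbright-out"
    # input: exactly one of the two
    noise: NoiseSpec | None = None
    images_dir: str | None = None
    pixel_size: float = 1.0  # arcmin, for directory input
    # contrast stage
    sigma_c: float = 4.0  # arcmin
    surround_ratio: float = 2.0  # sigma_s / sigma_c
    definition: str = "weber"  # weber | michelson | lowpass_weber
    lowpass_sigma: float = 8.0  # arcmin, for lowpass_weber
    # summaries
    with_fourier: bool = True
    with_depth: bool = False
    with_rgc: bool = False
    pm_weight: float = 9.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.noise is None) == (self.images_dir is None):
            raise ValueError("config must set exactly one of noise / images_dir")
        if self.definition not in ("weber", "michelson", "lowpass_weber"):
            raise ValueError("unknown contrast definition")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "noise" in raw and raw["noise"] is not None:
            noise = dict(raw["noise"])
            if "size" in noise:
                noise["size"] = tuple(noise["size"])
            raw["noise"] = NoiseSpec(**noise)
        return cls(**raw)


def _load_inputs(config: RunConfig):
    if config.noise is not None:
        spec = dataclasses.replace(config.noise, seed=config.seed)
        logger.info("generating %d class-%d noise pairs at %s", spec.n_images, spec.noise_class, spec.size)
        return generate_noise(spec)
    images = []
    for path in sorted(Path(config.images_dir).iterdir()):
        if path.suffix.lower() in RASTER_SUFFIXES:
            images.append(read_raster(path, pixel_size=config.pixel_size))
    if not images:
        raise FileNotFoundError(f"no supported rasters in {config.images_dir}")
    logger.info("loaded %d images from %s (dataset-dependent results)", len(images), config.images_dir)
    return [(im, None) for im in images]


def _distribution_frame(dists: list[FeatureDistribution]) -> pd.DataFrame:
    rows = []
    for d in dists:
        for c, amp, dens in zip(d.bin_centers, d.amplitude, d.density if d.density is not None else d.amplitude * np.nan):
            rows.append(
                {"feature": d.feature, "bin_center": c, "amplitude": amp,
                 "density": dens, "polarity": d.polarity, "units": d.units}
            )
    return pd.DataFrame(rows)


def _ratio_frame(curves: list[RatioCurve]) -> pd.DataFrame:
    rows = []
    for r in curves:
        for c, v, ex in zip(r.bin_centers, r.ratio, r.excluded_mask):
            rows.append(
                {"feature": r.feature, "bin_center": c, "dark_bright_ratio": v,
                 "excluded": bool(ex), "units": r.units}
            )
    return pd.DataFrame(rows)


def contrast_stage(config: RunConfig, images: list[LuminanceImage]) -> list[ContrastMap]:
    """Apply the configured contrast definition to every image."""
    if config.definition == "lowpass_weber":
        return [weber_lowpass_contrast(im, config.lowpass_sigma) for im in images]
    op = make_operator(
        DogSpec(config.sigma_c, config.surround_ratio * config.sigma_c),
        pixel_size=images[0].pixel_size,
        definition=config.definition,
    )
    lut = op.lookup(config.definition)
    return [to_equivalent_contrast(apply_operator(im, op), lut, config.definition) for im in images]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write CSV/JSON outputs.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Any stage failure aborts with the stage named in the log.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "outputs": [],
        "dataset_dependent": config.images_dir is not None,
    }

    stage = "input"
    try:
        pairs = _load_inputs(config)
        images = [im for im, _ in pairs]

        stage = "contrast"
        cmaps = contrast_stage(config, images)
        manifest["clamped_fraction_mean"] = float(np.mean([m.clamped_fraction for m in cmaps]))
        splits = [split_bright_dark(m) for m in cmaps]

        stage = "features"
        bright = contrast_distribution(cmaps, "bright")
        dark = contrast_distribution(cmaps, "dark")
        normalize_pair(bright, dark)
        dists = [bright, dark]
        ratios = [dark_bright_ratio(dark, bright)]
        if config.with_fourier:
            sf_b, ori_b, dc_b = ensemble_fourier_distributions(
                [b for b, _ in splits], polarity="bright"
            )
            sf_d, ori_d, dc_d = ensemble_fourier_distributions(
                [d for _, d in splits], polarity="dark"
            )
            normalize_pair(sf_b, sf_d)
            normalize_pair(ori_b, ori_d)
            dists += [sf_b, sf_d, ori_b, ori_d]
            ratios.append(dark_bright_ratio(sf_d, sf_b))
            ratios.append(dark_bright_ratio(ori_d, ori_b, dc_pair=(dc_d, dc_b)))
            manifest["dc_amplitude"] = {"bright": dc_b, "dark": dc_d}
        if config.with_depth:
            if any(dm is None for _, dm in pairs):
                raise ValueError("depth summaries need paired distance maps")
            op = make_operator(
                DogSpec(config.sigma_c, config.surround_ratio * config.sigma_c),
                pixel_size=images[0].pixel_size,
            )
            depth_d, depth_b = ensemble_relative_depth(pairs, op)
            dists += [depth_b, depth_d]
            ratios.append(dark_bright_ratio(depth_d, depth_b))

        _distribution_frame(dists).to_csv(out / "distributions.csv", index=False)
        _ratio_frame(ratios).to_csv(out / "ratio_curves.csv", index=False)
        manifest["outputs"] += ["distributions.csv", "ratio_curves.csv"]

        if config.with_rgc:
            stage = "rgc"
            from .rgc import off_bias

            summary = off_bias(images, pm_weight=config.pm_weight)
            manifest["rgc"] = {
                "off_bias_overall": summary.off_bias_overall,
                "off_bias_by_class": {f"{p}-{l}": v for (p, l), v in summary.off_bias_by_class.items()},
                "pm_weight": config.pm_weight,
            }
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote %s", out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# reduced-scale figure reproduction on synthetic inputs

FIGURES = ("fig1", "fig3-noise", "fig4", "fig5-noise", "fig6", "fig7")


def reproduce_figures(which=FIGURES, scale: float = 0.25, out_dir: str = "figures", seed: int = 0) -> list[Path]:
    """Render reduced-scale analogues of the main figures on synthetic data.

    ``scale`` shrinks the ensemble (image count and side length) relative
    to the full 25 x 1024^2 conditions.  Natural-image panels are only
    rendered from user-supplied data via :func:`run_pipeline`; here all
    inputs are synthetic.  Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = max(3, int(round(25 * scale)))
    size = max(256, int(round(1024 * scale)))
    written = []

    def _ensemble(noise_class):
        spec = NoiseSpec(noise_class=noise_class, n_images=n, size=(size, size), seed=seed)
        return generate_noise(spec)

    def _feature_panels(pairs, title, path, with_depth):
        images = [im for im, _ in pairs]
        op = make_operator(DogSpec(4.0, 8.0), pixel_size=images[0].pixel_size)
        cmaps = [to_equivalent_contrast(apply_operator(im, op), op.lookup_weber) for im in images]
        splits = [split_bright_dark(m) for m in cmaps]
        bright = contrast_distribution(cmaps, "bright")
        dark = contrast_distribution(cmaps, "dark")
        normalize_pair(bright, dark)
        sf_b, ori_b, dc_b = ensemble_fourier_distributions([b for b, _ in splits])
        sf_d, ori_d, dc_d = ensemble_fourier_distributions([d for _, d in splits])
        normalize_pair(sf_b, sf_d)
        normalize_pair(ori_b, ori_d)
        panels = [("contrast (%)", bright, dark), ("spatial frequency (cpd)", sf_b, sf_d), ("orientation (deg)", ori_b, ori_d)]
        if with_depth:
            depth_d, depth_b = ensemble_relative_depth(pairs, op)
            panels.append(("relative depth (D)", depth_b, depth_d))
        fig, axes = plt.subplots(2, len(panels), figsize=(4 * len(panels), 6))
        for ax_top, ax_bot, (label, b, d) in zip(axes[0], axes[1], panels):
            ax_top.plot(b.bin_centers, b.density, "r-", label="bright")
            ax_top.plot(d.bin_centers, d.density, "b--", label="dark")
            ax_top.set_xlabel(label)
            ax_top.set_ylabel("probability density")
            ax_top.legend(fontsize=7)
            if b.feature == "spatial_frequency":
                ax_top.set_xscale("log")
            curve = dark_bright_ratio(d, b, dc_pair=(dc_d, dc_b) if b.feature == "orientation" else None)
            ax_bot.plot(curve.bin_centers, curve.ratio, "k-")
            ax_bot.axhline(1.0, ls="--", c="gray")
            ax_bot.set_xlabel(label)
            ax_bot.set_ylabel("dark/bright ratio")
            if b.feature == "spatial_frequency":
                ax_bot.set_xscale("log")
        fig.suptitle(title)
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    for name in which:
        if name == "fig1":
            from .synthetic import generate_random_baselines

            images, _ = generate_random_baselines(n, (size, size), seed)
            op = make_operator(DogSpec(4.0, 8.0))
            cmaps = [to_equivalent_contrast(apply_operator(im, op), op.lookup_weber) for im in images]
            dist = contrast_distribution(cmaps, "all")
            sf, ori, _ = ensemble_fourier_distributions([im.values for im in images], pixel_size=1.0)
            fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
            axes[0].plot(dist.bin_centers, dist.amplitude / dist.amplitude.sum())
            axes[0].set_xlabel("contrast (%)")
            axes[1].loglog(sf.bin_centers, sf.amplitude)
            axes[1].set_xlabel("spatial frequency (cpd)")
            axes[2].plot(ori.bin_centers, ori.amplitude)
            axes[2].set_xlabel("orientation (deg)")
            for ax in axes:
                ax.set_ylabel("amplitude / frequency")
            fig.suptitle("first-order distributions, random baselines")
            fig.tight_layout()
            path = out / "fig1.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)
        elif name in ("fig3-noise", "fig4"):
            _feature_panels(_ensemble(5), "naturalistic (class 5) noise", out / f"{name}.png", with_depth=True)
            if name == "fig4":
                _feature_panels(_ensemble(1), "white (class 1) noise", out / "fig4-white.png", with_depth=True)
        elif name == "fig5-noise":
            from .rgc import off_bias

            pairs = _ensemble(3)
            summary = off_bias([im for im, _ in pairs][: max(2, n // 2)])
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
            keys = list(summary.off_bias_by_class)
            ax1.bar(range(len(keys)), [summary.off_bias_by_class[k] for k in keys])
            ax1.set_xticks(range(len(keys)), [f"{p}\n{l}" for p, l in keys], fontsize=7)
            ax1.axhline(1.0, ls="--", c="gray")
            ax1.set_ylabel("OFF/ON amplitude ratio")
            for key, (centers, ratio) in summary.contrast_off_bias.items():
                ax2.plot(np.abs(centers), ratio, label=f"{key[0]}-{key[1]}", alpha=0.7)
            ax2.set_xlabel("|contrast| (%)")
            ax2.set_ylabel("OFF/ON bias")
            ax2.legend(fontsize=7)
            fig.suptitle("RGC afferent OFF bias, skewed 1/f noise")
            fig.tight_layout()
            path = out / "fig5-noise.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)
        elif name == "fig6":
            from .rgc import bar_afferent_ratio
            from .synthetic import generate_bar

            ratio = bar_afferent_ratio(100.0)
            fig, axes = plt.subplots(1, 3, figsize=(9, 3))
            for ax, pol in zip(axes[:2], ("bright", "dark")):
                ax.imshow(generate_bar(pol).values, cmap="gray", vmin=0, vmax=1)
                ax.set_title(f"{pol} bar")
                ax.axis("off")
            axes[2].bar([0, 1], [1.0, ratio], tick_label=["bright", "dark"])
            axes[2].set_ylabel("relative afferent signal")
            axes[2].set_title(f"dark/bright = {ratio:.2f}")
            fig.tight_layout()
            path = out / "fig6.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)
            print(f"fig6: dark/bright afferent ratio = {ratio:.2f}")
        elif name == "fig7":
            from .population import TuningPopulation, discrimination_bound, fisher_information

            pop_d = TuningPopulation.uniform(25, 1.0, 25.0)
            pop_b = TuningPopulation.uniform(25, 1.0, 12.5)
            grid = pop_d.interior_grid()
            F_d, F_b = fisher_information(pop_d, grid), fisher_information(pop_b, grid)
            b_d, b_b = discrimination_bound(F_d), discrimination_bound(F_b, dark_curve=F_d)
            fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
            s = np.linspace(grid[0], grid[-1], 400)
            from .population import population_response

            axes[0].plot(s, population_response(s, pop_d), "b-", lw=0.6)
            axes[0].plot(s, population_response(s, pop_b), "r-", lw=0.6)
            axes[0].set_xlabel("feature s")
            axes[0].set_ylabel("rate (spikes/s)")
            axes[1].plot(grid, F_d.F, "b-", label="dark")
            axes[1].plot(grid, F_b.F, "r-", label="bright")
            axes[1].set_ylabel("Fisher information")
            axes[1].legend()
            axes[2].plot(grid, b_d.delta, "b-", label="dark")
            axes[2].plot(grid, b_b.delta, "r-", label="bright")
            axes[2].set_ylabel("threshold lower bound")
            axes[2].legend()
            for ax in axes[1:]:
                ax.set_xlabel("feature s")
            fig.tight_layout()
            path = out / "fig7.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(path)
        else:
            raise ValueError(f"unknown figure {name!r}; choose from {FIGURES}")
    return written
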