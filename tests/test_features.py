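"""Feature distributions: overlapping histograms, Fourier masks, depth."""

import numpy as np
import pytest

from darkbright.contrast import ContrastMap, DogSpec, make_operator
from darkbright.features import (
    DEPTH_BIN_STEP,
    DEPTH_BIN_WIDTH,
    FeatureDistribution,
    _band_weights,
    _wedge_weights,
    contrast_distribution,
    dark_bright_ratio,
    ensemble_fourier_distributions,
    fourier_distributions,
    normalize_pair,
    overlapping_histogram,
    radial_amplitude_slope,
    relative_depth_distribution,
)
from darkbright.io import DistanceMap, LuminanceImage


class TestContrastDistribution:
    def test_all_zero_map_is_empty(self):
        dist = contrast_distribution(ContrastMap(np.zeros((4, 4)), "weber", 1.0), "all")
        assert dist.amplitude.sum() == 0

    def test_hand_enumerated_overlapping_bins(self):
        # values {10, 10, 40}: with 5.4-wide bins every 2.7, value 10 falls
        # in the bins centered 8.1 and 10.8 only, value 40 in 37.8 and 40.5
        cmap = ContrastMap(np.array([[10.0, 10.0, 40.0]]), "weber", 1.0)
        dist = contrast_distribution(cmap, "all")
        expected = {8.1: 2, 10.8: 2, 37.8: 1, 40.5: 1}
        for c, amp in zip(dist.bin_centers, dist.amplitude):
            assert amp == expected.get(round(c, 1), 0)

    def test_dark_binned_by_magnitude(self):
        cmap = ContrastMap(np.array([[-10.0, 10.0]]), "weber", 1.0)
        dark = contrast_distribution(cmap, "dark")
        bright = contrast_distribution(cmap, "bright")
        np.testing.assert_array_equal(dark.amplitude, bright.amplitude)

    def test_joint_normalization_integrates_to_one(self, white_noise_maps):
        bright = contrast_distribution(white_noise_maps, "bright")
        dark = contrast_distribution(white_noise_maps, "dark")
        normalize_pair(bright, dark)
        total = (bright.density.sum() + dark.density.sum()) * bright.bin_step
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_bright_equals_dark(self, white_noise_maps):
        # symmetric where the mass lives; the rare tail inherits the
        # (real) bright/dark asymmetry of the equivalent-contrast lookup
        bright = contrast_distribution(white_noise_maps, "bright")
        dark = contrast_distribution(white_noise_maps, "dark")
        normalize_pair(bright, dark)
        dense = (bright.density > 1e-3) & (dark.density > 1e-3)
        assert dense.sum() >= 3
        ratio = dark.amplitude[dense] / bright.amplitude[dense]
        assert np.all(np.abs(ratio - 1) < 0.1)

    def test_permutation_invariance(self, white_noise_maps):
        a = contrast_distribution(white_noise_maps, "dark")
        b = contrast_distribution(white_noise_maps[::-1], "dark")
        np.testing.assert_array_equal(a.amplitude, b.amplitude)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            contrast_distribution([], "all")


class TestOverlappingHistogram:
    def test_weighted_counts(self):
        vals = np.array([1.0, 2.0, 3.0])
        w = np.array([0.5, 1.0, 2.0])
        out = overlapping_histogram(vals, np.array([2.0]), 2.5, weights=w)
        # bin [0.75, 3.25) catches all three
        assert out[0] == pytest.approx(3.5)

    def test_half_open_edges(self):
        out = overlapping_histogram(np.array([1.0]), np.array([0.0, 2.0]), 2.0)
        # [−1,1) excludes 1.0; [1,3) includes it
        assert out.tolist() == [0.0, 1.0]


class TestFourierDistributions:
    def test_white_noise_orientation_uniform(self, rng):
        maps = [rng.standard_normal((128, 128)) for _ in range(6)]
        _, ori, _ = ensemble_fourier_distributions(maps, pixel_size=1.0)
        dev = ori.amplitude / ori.amplitude.mean() - 1
        assert np.max(np.abs(dev)) < 0.1

    def test_grating_peaks_in_matching_ring_and_wedge(self):
        n, cycles = 128, 16.0
        x = np.arange(n)
        img = np.sin(2 * np.pi * cycles * x / n)[None, :].repeat(n, axis=0)
        sf, ori, _ = fourier_distributions(img, pixel_size=1.0)
        f0 = cycles / (n * (1 / 60))  # cpd
        assert abs(sf.bin_centers[np.argmax(sf.amplitude)] - f0) / f0 < 0.15
        # grating varying along x -> spectral energy on the horizontal
        # frequency axis (theta = 0)
        assert ori.bin_centers[np.argmax(ori.amplitude)] == 0.0

    def test_ring_and_wedge_means_match_brute_force(self, rng):
        """Mask-weighted means recomputed per pixel with explicit loops."""
        arr = rng.standard_normal((32, 32))
        sf, ori, _ = fourier_distributions(arr, pixel_size=1.0, n_rings=5)
        spec = np.abs(np.fft.fftshift(np.fft.fft2(arr * _hanning(32)))) / 32**2
        px_deg = 1 / 60
        f_1d = np.fft.fftshift(np.fft.fftfreq(32)) / px_deg
        f_pixel = 1.0 / (32 * px_deg)
        ratio = (sf.meta["f_hi"] / sf.meta["f_lo"]) ** (1 / 8)  # sqrt of ring step
        for k in [0, 2, 4]:
            c = sf.bin_centers[k]
            num = den = 0.0
            for i in range(32):
                for j in range(32):
                    if (i, j) == (16, 16):
                        continue
                    f = np.hypot(f_1d[i], f_1d[j])
                    w = _band_weights(np.array([f]), c / ratio, c * ratio, f_pixel)[0]
                    num += w * spec[i, j]
                    den += w
            assert sf.amplitude[k] == pytest.approx(num / den, rel=1e-9)

    def test_wedge_masks_tile_the_annulus(self, rng):
        # 36 non-overlapping anti-aliased 5-degree sectors sum to the
        # unmasked annulus total
        f_1d = np.fft.fftshift(np.fft.fftfreq(64))
        f = np.hypot(f_1d[:, None], f_1d[None, :])
        theta = np.degrees(np.arctan2(f_1d[:, None], f_1d[None, :])) % 180.0
        annulus = _band_weights(f, 0.1, 0.4, 1 / 64)
        annulus[32, 32] = 0.0
        spec = rng.uniform(0.5, 1.5, (64, 64))
        ramp = np.where(f > 0, (1 / 64) / np.maximum(f, 1e-12), np.inf)
        total = np.zeros_like(spec)
        for c in np.arange(0.0, 180.0, 5.0):
            total += _wedge_weights(theta, c, 2.5, np.degrees(ramp))
        np.testing.assert_allclose((total * annulus * spec).sum(), (annulus * spec).sum(), rtol=1e-9)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            fourier_distributions(np.ones((8, 8)), pixel_size=1.0)


def _hanning(n):
    x = np.arange(n) - (n - 1) / 2
    r = np.hypot(x[:, None], x[None, :])
    return 0.5 * (1 + np.cos(np.pi * np.minimum(r / (n / 2), 1.0)))


class TestDarkBrightRatio:
    def _dist(self, amp, polarity):
        return FeatureDistribution(
            "contrast", np.arange(len(amp), dtype=float), np.array(amp, dtype=float),
            1.0, polarity=polarity,
        )

    def test_identical_distributions_give_unity(self):
        d, b = self._dist([2, 4, 2], "dark"), self._dist([2, 4, 2], "bright")
        curve = dark_bright_ratio(d, b)
        np.testing.assert_allclose(curve.ratio[~curve.excluded_mask], 1.0)

    def test_doubled_dark_gives_two(self):
        d, b = self._dist([4, 8, 4], "dark"), self._dist([2, 4, 2], "bright")
        curve = dark_bright_ratio(d, b)
        np.testing.assert_allclose(curve.ratio[~curve.excluded_mask], 2.0)

    def test_low_density_bins_excluded(self):
        d, b = self._dist([1e6, 1e-3, 1e6], "dark"), self._dist([1e6, 1e6, 1e6], "bright")
        curve = dark_bright_ratio(d, b)
        assert curve.excluded_mask.tolist() == [False, True, False]

    def test_dc_readdition_shifts_ratio(self):
        d, b = self._dist([1.0, 1.0], "dark"), self._dist([1.0, 1.0], "bright")
        curve = dark_bright_ratio(d, b, dc_pair=(1.0, 3.0))
        np.testing.assert_allclose(curve.ratio, (1 + 1) / (1 + 3))

    def test_all_excluded_raises(self):
        d, b = self._dist([1e-9, 1e-9], "dark"), self._dist([1.0, 1.0], "bright")
        with pytest.raises(ValueError, match="excluded"):
            dark_bright_ratio(d, b)


@pytest.fixture(scope="module")
def small_op():
    return make_operator(DogSpec(1.0, 2.0))


class TestRelativeDepth:
    def test_constant_distance_map(self, small_op, rng):
        img = LuminanceImage(rng.uniform(0.5, 1.5, (40, 40)))
        dmap = DistanceMap(np.full((40, 40), 10.0), pixel_size=1.0)
        dark, bright = relative_depth_distribution(img, dmap, small_op)
        # all relative depths are exactly zero -> mass only in bins
        # whose support includes zero
        for dist in (dark, bright):
            nonzero = dist.amplitude > 0
            assert np.all(np.abs(dist.bin_centers[nonzero]) < DEPTH_BIN_WIDTH / 2)

    def test_step_map_matches_per_pixel_oracle(self, small_op, rng):
        """Distribution equals an explicit per-pixel recomputation."""
        from darkbright.features import _relative_depth_samples

        n = 32
        img = LuminanceImage(rng.uniform(0.5, 1.5, (n, n)))
        dvals = np.where(np.arange(n)[None, :] < n // 2, 10.0, 20.0) * np.ones((n, n))
        mask = rng.uniform(size=(n, n)) > 0.1  # some invalid pixels
        dmap = DistanceMap(dvals, valid_mask=mask, pixel_size=1.0)
        rel, con = _relative_depth_samples(img, dmap, small_op)

        # oracle: direct loops over the smoothing kernel
        sigma = 30.0
        hw = int(np.ceil(4 * sigma))
        ax = np.arange(-hw, hw + 1)
        k1 = np.exp(-0.5 * (ax / sigma) ** 2)
        k1 /= k1.sum()
        kern = np.outer(k1, k1)
        pad_v = np.zeros((n + 2 * hw, n + 2 * hw))
        pad_m = np.zeros_like(pad_v)
        pad_v[hw : hw + n, hw : hw + n] = np.where(mask, dvals, 0.0)
        pad_m[hw : hw + n, hw : hw + n] = mask
        ophw = small_op.half_width
        expected = []
        for i in range(ophw, n - ophw):
            for j in range(ophw, n - ophw):
                if not mask[i, j]:
                    continue
                wsum = (kern * pad_m[i : i + 2 * hw + 1, j : j + 2 * hw + 1]).sum()
                vsum = (kern * pad_v[i : i + 2 * hw + 1, j : j + 2 * hw + 1]).sum()
                expected.append(1.0 / (vsum / wsum) - 1.0 / dvals[i, j])
        np.testing.assert_allclose(np.sort(rel), np.sort(expected), atol=1e-10)
        assert rel.size == con.size

    def test_far_pixels_positive(self, small_op, rng):
        # a single far column inside a near field must produce positive
        # relative depth at that column
        n = 40
        img = LuminanceImage(rng.uniform(0.5, 1.5, (n, n)))
        dvals = np.full((n, n), 10.0)
        dvals[:, n // 2] = 40.0
        from darkbright.features import _relative_depth_samples

        rel, _ = _relative_depth_samples(img, DistanceMap(dvals), small_op)
        rel_grid = rel.reshape(n - 2 * small_op.half_width, -1)
        far_col = n // 2 - small_op.half_width
        assert np.all(rel_grid[:, far_col] > 0)


def test_radial_slope_recovers_imposed_exponent(rng):
    from darkbright.synthetic import _shape_spectrum

    field = _shape_spectrum(rng.standard_normal((512, 512)), 1.0)
    slope = radial_amplitude_slope(field, 8, 80)
    assert slope == pytest.approx(-1.0, abs=0.05)
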