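"""Contrast operators: kernels, divisive normalization, spot calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darkbright.contrast import (
    ContrastMap,
    DogSpec,
    apply_operator,
    build_lookup,
    disc_mask,
    dog_fwhm,
    make_operator,
    split_bright_dark,
    to_equivalent_contrast,
    weber_lowpass_contrast,
)
from darkbright.io import LuminanceImage
from darkbright.synthetic import generate_spot


def direct_normalized_dog(lum, op):
    """Independent spatial-domain evaluation of the normalized DOG.

    Accumulates shifted copies of the image weighted by each kernel tap --
    no FFT anywhere -- and divides pointwise.
    """
    hw = op.half_width
    h, w = lum.shape
    out_shape = (h - 2 * hw, w - 2 * hw)
    num = np.zeros(out_shape)
    den = np.zeros(out_shape)
    dog, norm = op.kernel_dog, op.kernel_normalizer
    for dy in range(2 * hw + 1):
        for dx in range(2 * hw + 1):
            patch = lum[dy : dy + out_shape[0], dx : dx + out_shape[1]]
            # convolution flips the kernel relative to correlation
            num += dog[2 * hw - dy, 2 * hw - dx] * patch
            den += norm[2 * hw - dy, 2 * hw - dx] * patch
    return num / den


class TestKernels:
    @pytest.mark.parametrize("sc, ss", [(4.0, 8.0), (2.0, 3.0), (8.0, 32.0)])
    def test_unit_and_zero_sums(self, sc, ss):
        op = make_operator(DogSpec(sc, ss), build_lookups=False)
        assert abs(op.kernel_center.sum() - 1) < 1e-10
        assert abs(op.kernel_surround.sum() - 1) < 1e-10
        assert abs(op.kernel_normalizer.sum() - 1) < 1e-10
        assert abs(op.kernel_dog.sum()) < 1e-10

    def test_normalizer_defaults_to_surround(self):
        spec = DogSpec(4.0, 8.0)
        assert spec.sigma_n == spec.sigma_s

    def test_fwhm_matches_dense_radial_sampling(self):
        # independent oracle: dense radial sampling plus bisection between
        # the two samples bracketing the half-max crossing
        sc, ss = 4.0, 8.0
        r = np.linspace(0, 20, 100_000)
        prof = np.exp(-0.5 * (r / sc) ** 2) / (2 * np.pi * sc**2) - np.exp(
            -0.5 * (r / ss) ** 2
        ) / (2 * np.pi * ss**2)
        half = prof[0] / 2
        i = np.argmax(prof < half)
        lo, hi = r[i - 1], r[i]
        for _ in range(60):
            mid = (lo + hi) / 2
            val = np.exp(-0.5 * (mid / sc) ** 2) / (2 * np.pi * sc**2) - np.exp(
                -0.5 * (mid / ss) ** 2
            ) / (2 * np.pi * ss**2)
            if val > half:
                lo = mid
            else:
                hi = mid
        assert dog_fwhm(sc, ss) == pytest.approx(2 * lo, abs=1e-8)

    def test_undersampled_kernel_warns(self):
        with pytest.warns(UserWarning, match="under-sampled"):
            make_operator(DogSpec(0.5, 1.5), build_lookups=False)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DogSpec(8.0, 4.0)


class TestApplyOperator:
    def test_uniform_image_gives_zero(self, op48):
        img = LuminanceImage(np.full((80, 80), 7.3))
        out = apply_operator(img, op48)
        assert np.allclose(out.values, 0.0, atol=1e-12)
        assert out.values.shape == (80 - 2 * op48.half_width,) * 2

    def test_global_scale_invariance(self, op48, rng):
        lum = rng.uniform(0.5, 2.0, (80, 80))
        a = apply_operator(LuminanceImage(lum), op48).values
        b = apply_operator(LuminanceImage(1e3 * lum), op48).values
        assert np.max(np.abs(a - b)) < 1e-10 * np.max(np.abs(a))

    def test_matches_direct_spatial_loop(self, rng):
        op = make_operator(DogSpec(2.0, 4.0), build_lookups=False)
        lum = rng.uniform(0.5, 2.0, (64, 64))
        fast = apply_operator(LuminanceImage(lum), op).values
        slow = direct_normalized_dog(lum, op)
        np.testing.assert_allclose(fast, slow, rtol=1e-8, atol=1e-12)

    def test_too_small_image_raises(self, op48):
        with pytest.raises(ValueError, match="smaller"):
            apply_operator(LuminanceImage(np.ones((16, 16))), op48)


class TestLookup:
    def test_background_spot_is_zero(self, op48):
        lut = op48.lookup_weber
        assert np.interp(0.0, lut.responses, lut.contrasts) == pytest.approx(0.0, abs=1e-9)

    def test_responses_strictly_increase(self, op48):
        assert np.all(np.diff(op48.lookup_weber.responses) > 0)

    def test_dark_spot_drives_harder_than_bright(self, op48):
        # the normalizer is raised by a bright spot and lowered by a dark
        # one, so equal |Weber| spots give asymmetric raw responses
        lut = op48.lookup_weber
        r_dark = np.interp(-50.0, lut.contrasts, lut.responses)
        r_bright = np.interp(50.0, lut.contrasts, lut.responses)
        assert abs(r_dark) > abs(r_bright)

    def test_node_identity_interpolation(self, op48):
        lut = op48.lookup_weber
        raw = ContrastMap(lut.responses[123].reshape(1, 1), "raw", 1.0)
        eq = to_equivalent_contrast(raw, lut)
        assert eq.values[0, 0] == pytest.approx(lut.contrasts[123], abs=1e-12)

    @pytest.mark.parametrize("w", [-90.0, -30.0, 30.0, 90.0])
    def test_spot_round_trip_within_half_point(self, op48, w):
        spot = generate_spot(op48, 0.5 * (1 + w / 100))
        eq = to_equivalent_contrast(apply_operator(spot, op48), op48.lookup_weber)
        center = eq.values[eq.values.shape[0] // 2, eq.values.shape[1] // 2]
        assert abs(center - w) < 0.5

    def test_michelson_below_weber(self, op48):
        w = op48.lookup_weber.contrasts
        m = op48.lookup_michelson.contrasts
        neg, pos = w < 0, w > 0
        assert np.all(np.abs(m[neg]) <= np.abs(w[neg]) + 1e-9)
        assert np.all(m[pos] <= w[pos] + 1e-9)

    def test_out_of_range_clamped_and_counted(self, op48):
        lut = op48.lookup_weber
        raw = ContrastMap(
            np.array([[lut.responses[0] - 1.0, 0.0, lut.responses[-1] + 1.0, 0.0]]),
            "raw", 1.0,
        )
        eq = to_equivalent_contrast(raw, lut)
        assert eq.values[0, 0] == -100.0 and eq.values[0, 2] == 100.0
        assert eq.clamped_fraction == pytest.approx(0.5)


class TestWeberLowpass:
    def test_uniform_is_zero_and_scale_invariant(self, rng):
        img = LuminanceImage(np.full((70, 70), 3.0))
        assert np.allclose(weber_lowpass_contrast(img, 4.0).values, 0.0, atol=1e-12)
        lum = rng.uniform(0.5, 2.0, (70, 70))
        a = weber_lowpass_contrast(LuminanceImage(lum), 4.0).values
        b = weber_lowpass_contrast(LuminanceImage(7.0 * lum), 4.0).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_isolated_double_pixel_approaches_plus_100(self):
        # a pixel at 2x a flat surround: w = 100 * (2 - b) / b with
        # b = 1 + k0 where k0 is the kernel's center tap; as sigma grows
        # k0 -> 0 and w -> +100
        from darkbright.contrast import KERNEL_EXTENT_SIGMAS, gaussian_kernel_1d

        sigma = 10.0
        n = 2 * int(np.ceil(4 * sigma)) * 2 + 81
        lum = np.ones((n, n))
        lum[n // 2, n // 2] = 2.0
        cmap = weber_lowpass_contrast(LuminanceImage(lum), sigma)
        center = cmap.values[cmap.values.shape[0] // 2, cmap.values.shape[1] // 2]
        k1 = gaussian_kernel_1d(sigma, int(np.ceil(KERNEL_EXTENT_SIGMAS * sigma)))
        k0 = k1.max() ** 2
        expected = 100.0 * (2.0 - (1.0 + k0)) / (1.0 + k0)
        assert center == pytest.approx(expected, rel=1e-9)
        assert center > 95.0


class TestSplitBrightDark:
    def test_example(self):
        cmap = ContrastMap(np.array([[-3.0, 0.0, 5.0]]), "weber", 1.0)
        bright, dark = split_bright_dark(cmap)
        assert bright.values.tolist() == [[0.0, 0.0, 5.0]]
        assert dark.values.tolist() == [[-3.0, 0.0, 0.0]]

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=64))
    def test_exact_reconstruction_and_counts(self, vals):
        arr = np.array(vals).reshape(1, -1)
        cmap = ContrastMap(arr, "weber", 1.0)
        bright, dark = split_bright_dark(cmap)
        assert np.all(bright.values >= 0) and np.all(dark.values <= 0)
        np.testing.assert_array_equal(bright.values + dark.values, arr)
        n_pos = int(np.sum(bright.values > 0))
        n_neg = int(np.sum(dark.values < 0))
        n_zero = int(np.sum(arr == 0))
        assert n_pos + n_neg + n_zero == arr.size


def test_spot_disc_rasterization_rule(op48):
    # pixel-center membership: count equals the explicit enumeration
    radius = 0.5 * op48.fwhm_positive_lobe
    mask = disc_mask(op48.half_width, radius)
    count = 0
    for y in range(-op48.half_width, op48.half_width + 1):
        for x in range(-op48.half_width, op48.half_width + 1):
            if np.hypot(y, x) <= radius:
                count += 1
    assert mask.sum() == count
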