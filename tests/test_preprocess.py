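"""Preprocessing: resampling, SANLM denoising, Otsu masking, normalization,
augmentation — each against its brute-force oracle or closed form."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermapatch.preprocess import (
    PreprocessConfig, resample, sanlm_denoise, otsu_threshold, skin_mask,
    minmax_normalize, augment, preprocess_image,
)
from _oracles import nlm_reference, otsu_exhaustive


class TestResample:
    def test_upsample_fills_blocks(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = resample(img, (4, 4))
        expect = np.array([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]],
                          dtype=float)
        assert np.array_equal(out, expect)

    def test_identity_at_own_size(self, rng):
        img = rng.random((5, 7, 3))
        assert np.array_equal(resample(img, (5, 7)), img)

    def test_downsample_keeps_strided_positions(self, rng):
        img = rng.random((4, 4))
        out = resample(img, (2, 2))
        assert np.array_equal(out, img[::2, ::2])

    def test_nearest_introduces_no_new_values(self, rng):
        img = rng.random((10, 13, 3))
        out = resample(img, (7, 5))
        assert np.all(np.isin(out.ravel(), img.ravel()))

    def test_matches_coordinate_map_oracle(self, rng):
        img = rng.random((9, 6))
        th, tw = 5, 8
        out = resample(img, (th, tw))
        for x in range(th):
            for y in range(tw):
                assert out[x, y] == img[(x * 9) // th, (y * 6) // tw]

    def test_rejects_bad_target(self):
        with pytest.raises(ValueError):
            resample(np.zeros((4, 4)), (0, 4))


class TestSanlm:
    def test_constant_image_is_fixed_point(self):
        img = np.full((8, 8, 3), 0.37)
        out = sanlm_denoise(img, PreprocessConfig(sanlm_h=0.2))
        assert np.allclose(out, 0.37, atol=1e-12)

    def test_matches_double_loop_reference(self, rng):
        cfg = PreprocessConfig(sanlm_h=0.5, sanlm_patch_radius=1, sanlm_search_radius=2)
        img = rng.random((16, 16))
        out = sanlm_denoise(img, cfg)
        ref = nlm_reference(img, 0.5, 2, 1)
        assert np.abs(out - ref).max() < 1e-10

    def test_matches_reference_pixelwise_mode_rgb(self, rng):
        cfg = PreprocessConfig(sanlm_h=0.3, sanlm_patch_radius=0, sanlm_search_radius=2)
        img = rng.random((10, 12, 3))
        out = sanlm_denoise(img, cfg)
        ref = nlm_reference(img, 0.3, 2, 0)
        assert np.abs(out - ref).max() < 1e-10

    def test_output_range_within_input_range(self, rng):
        img = rng.random((12, 12, 3)) * 0.5 + 0.25
        out = sanlm_denoise(img)
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12

    def test_rejects_nonpositive_h(self):
        with pytest.raises(ValueError):
            sanlm_denoise(np.zeros((4, 4)), PreprocessConfig(sanlm_h=0.0))


class TestOtsu:
    def test_two_point_histogram(self):
        hist = np.zeros(256)
        hist[0], hist[255] = 10, 10
        t = otsu_threshold(hist)
        assert 0 <= t < 255
        assert t == otsu_exhaustive(hist)

    def test_symmetric_bimodal_splits_classes(self):
        hist = np.zeros(256)
        hist[50], hist[200] = 10, 10
        t = otsu_threshold(hist)
        assert 50 <= t < 200

    def test_matches_exhaustive_scan_on_random_histograms(self, rng):
        for _ in range(100):
            hist = rng.integers(0, 50, size=256)
            if np.count_nonzero(hist) < 2:
                continue
            assert otsu_threshold(hist) == otsu_exhaustive(hist)

    def test_degenerate_histogram_rejected(self):
        hist = np.zeros(256)
        hist[77] = 100
        with pytest.raises(ValueError):
            otsu_threshold(hist)


class TestSkinMask:
    def test_bimodal_image_masks_bright_half(self):
        img = np.full((10, 10, 3), 0.1)
        img[:, 5:] = 0.9
        sm = skin_mask(img)
        assert np.array_equal(sm.mask[:, 5:], np.ones((10, 5), dtype=np.uint8))
        assert np.array_equal(sm.mask[:, :5], np.zeros((10, 5), dtype=np.uint8))

    def test_apply_zeroes_background(self):
        img = np.full((6, 6, 3), 0.1)
        img[:3] = 0.9
        sm = skin_mask(img)
        seg = sm.apply(img)
        assert seg[3:].max() == 0.0
        assert np.array_equal(seg[:3], img[:3])

    def test_masking_is_idempotent(self, rng):
        img = rng.random((12, 12, 3))
        sm = skin_mask(img)
        once = sm.apply(img)
        assert np.array_equal(sm.apply(once), once)

    def test_forced_threshold_below_min_keeps_everything(self):
        img = np.where((np.arange(36).reshape(6, 6) % 2 == 0)[..., None],
                       np.full(3, 0.8), np.full(3, 0.9))
        sm = skin_mask(img, threshold=0.5)
        assert sm.mask.all()

    def test_constant_image_raises_with_context(self):
        with pytest.raises(ValueError, match="skin mask"):
            skin_mask(np.full((5, 5, 3), 0.4))


class TestNormalize:
    def test_linear_endpoints(self):
        clean = minmax_normalize(np.array([10.0, 20.0, 30.0]))
        assert np.allclose(clean.pixels, [0.0, 0.5, 1.0])
        assert clean.i_min == 10 and clean.i_max == 30

    def test_idempotent(self, rng):
        img = rng.random((8, 8, 3)) * 5 + 1
        once = minmax_normalize(img)
        twice = minmax_normalize(once.pixels)
        assert np.allclose(once.pixels, twice.pixels, atol=1e-12)

    def test_constant_image_flags_degenerate(self):
        clean = minmax_normalize(np.full((4, 4), 3.0))
        assert clean.degenerate
        assert np.all(clean.pixels == 0.0)


class TestAugment:
    def test_zero_rotation_is_identity(self, rng):
        img = rng.random((9, 9, 3))
        assert np.allclose(augment(img, "rotate", theta=0.0), img)

    def test_hflip_is_involution(self, rng):
        img = rng.random((6, 8, 3))
        assert np.array_equal(augment(augment(img, "hflip"), "hflip"), img)
        assert np.array_equal(augment(augment(img, "vflip"), "vflip"), img)

    def test_quarter_turn_matches_coordinate_oracle(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = augment(img, "rotate", theta=90.0)
        assert np.array_equal(out, np.array([[2.0, 4.0], [1.0, 3.0]]))

    def test_brightness_scales_and_clips(self):
        img = np.array([[0.2, 0.6]])
        out = augment(img, "brightness", s=2.0)
        assert np.allclose(out, [[0.4, 1.0]])
        with pytest.raises(ValueError):
            augment(img, "brightness", s=0.0)

    def test_crop_bounds_checked(self, rng):
        img = rng.random((8, 8, 3))
        sub = augment(img, "crop", top=2, left=3, height=4, width=5)
        assert np.array_equal(sub, img[2:6, 3:8])
        with pytest.raises(ValueError):
            augment(img, "crop", top=6, left=0, height=4, width=4)


class TestPipeline:
    def test_pipeline_is_deterministic_and_in_range(self, rng):
        img = rng.random((40, 40, 3))
        cfg = PreprocessConfig(target_size=(32, 32))
        a = preprocess_image(img, cfg)
        b = preprocess_image(img, cfg)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.shape == (32, 32, 3)
        assert a.pixels.min() >= 0.0 and a.pixels.max() <= 1.0
        assert a.steps == ("resample", "denoise", "mask", "normalize")

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            preprocess_image(np.full((8, 8, 3), np.nan))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(2, 40), st.integers(2, 40), st.integers(1, 12))
def test_resample_shape_law(h, w, t):
    img = np.arange(h * w, dtype=float).reshape(h, w)
    assert resample(img, (t, t)).shape == (t, t)
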