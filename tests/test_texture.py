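"""Texture maps, Laplacian pyramid, and ground-truth composition."""

import numpy as np
import pytest

from oracles import expand_loop, gaussian_blur_loop, reduce_loop
from skintex.texture import (GRAY_WEIGHTS, build_pyramid,
                             compose_ground_truth, expand, make_ground_truth,
                             pore_band_signal, pore_texture_map, reduce_level,
                             to_grayscale, wrinkle_texture_map)


class TestGrayscale:
    def test_primary_colors(self):
        white = np.ones((2, 2, 3))
        assert np.allclose(to_grayscale(white), 1.0)
        green = np.zeros((2, 2, 3))
        green[..., 1] = 1.0
        assert np.allclose(to_grayscale(green), 0.587)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8, 3))
        expected = np.array(
            [[img[r, c] @ GRAY_WEIGHTS for c in range(8)] for r in range(8)]
        )
        assert np.allclose(to_grayscale(img), expected, atol=1e-12)

    def test_wrong_channels_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 4)))


class TestWrinkleMap:
    @pytest.mark.parametrize("c", [0.0, 0.25, 0.5, 1.0])
    def test_constant_image_closed_form(self, c):
        """Blur of a constant is the constant, so T = 255/(1+c) exactly."""
        img = np.full((40, 40), c)
        t = wrinkle_texture_map(img, sigma=3.0)
        assert np.allclose(t, 255.0 / (1.0 + c), atol=1e-9)

    def test_dark_pixel_against_convolution_oracle(self):
        img = np.full((33, 33), 0.8)
        img[16, 16] = 0.0
        t = wrinkle_texture_map(img, sigma=2.0)
        assert t[16, 16] == pytest.approx(255.0, abs=1e-9)  # I=0 there
        blur = gaussian_blur_loop(img, 2.0)
        expected = np.clip((1.0 - img / (1.0 + blur)) * 255.0, 0, 255)
        assert np.abs(t - expected).max() < 1e-5

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            wrinkle_texture_map(np.zeros((8, 8)), sigma=0.0)


class TestPyramid:
    def test_uniform_image_has_zero_laplacians(self):
        pyr = build_pyramid(np.full((33, 32), 0.5), 4)
        for lap in pyr.laplacian_levels:
            assert np.abs(lap).max() == 0.0

    def test_defining_identity_and_reconstruction(self):
        rng = np.random.default_rng(1)
        img = rng.random((37, 41))
        pyr = build_pyramid(img, 4)
        g0, g1 = pyr.gaussian_levels[:2]
        assert np.allclose(
            g0, pyr.laplacian_levels[0] + expand(g1, g0.shape), atol=1e-12
        )
        assert np.abs(pyr.reconstruct() - img).max() < 1e-6

    def test_level_sizes_halve_with_ceil(self):
        pyr = build_pyramid(np.zeros((37, 41)), 4)
        shapes = [g.shape for g in pyr.gaussian_levels]
        assert shapes == [(37, 41), (19, 21), (10, 11), (5, 6)]

    def test_impulse_matches_loop_oracle(self):
        img = np.zeros((16, 16))
        img[7, 8] = 1.0
        red = reduce_level(img)
        assert np.abs(red - reduce_loop(img)).max() < 1e-12
        exp = expand(red, img.shape)
        assert np.abs(exp - expand_loop(red, img.shape)).max() < 1e-12
        pyr = build_pyramid(img, 3)
        oracle_l0 = img - expand_loop(reduce_loop(img), img.shape)
        assert np.abs(pyr.laplacian_levels[0] - oracle_l0).max() < 1e-12

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="level"):
            build_pyramid(np.zeros((4, 4)), 5)


class TestPoreMap:
    def test_uniform_image_zero(self):
        assert np.abs(pore_texture_map(np.full((32, 32), 0.7), 0.01)).max() == 0.0

    def test_threshold_above_signal_kills_everything(self):
        rng = np.random.default_rng(2)
        img = rng.random((32, 32))
        tmax = np.abs(pore_band_signal(img)).max()
        assert np.abs(pore_texture_map(img, tmax * 1.01)).max() == 0.0

    def test_dark_pit_support_and_oracle(self):
        img = np.full((32, 32), 0.6)
        rr, cc = np.ogrid[:32, :32]
        img = img - 0.4 * np.exp(-((rr - 15) ** 2 + (cc - 17) ** 2) / (2 * 1.2**2))
        t = pore_band_signal(img)
        # oracle: the same band signal from loop-based reduce/expand
        g1 = reduce_loop(img)
        g2 = reduce_loop(g1)
        l0 = img - expand_loop(g1, img.shape)
        l1 = g1 - expand_loop(g2, g1.shape)
        t_oracle = -l0 + expand_loop(l1, img.shape)
        assert np.abs(t - t_oracle).max() < 1e-12
        tm = pore_texture_map(img, 0.01)
        assert tm[15, 17] > 0
        support = tm > 0
        assert support.sum() < 120  # a small blob, not the whole image
        assert support[15, 17]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_support_shrinks_monotonically_with_threshold(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((40, 40))
        prev = None
        for th in (0.0, 0.01, 0.05, 0.1, 0.3):
            support = pore_texture_map(img, th) > 0
            if prev is not None:
                assert (support <= prev).all()
            prev = support

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            pore_texture_map(np.zeros((16, 16)), -0.1)


class TestGroundTruth:
    def test_annotation_masks_texture(self):
        rng = np.random.default_rng(3)
        tex = rng.random((16, 16)) * 255
        ones = np.ones((16, 16), bool)
        zeros = np.zeros((16, 16), bool)
        assert np.array_equal(compose_ground_truth(tex, ones), tex)
        assert np.abs(compose_ground_truth(tex, zeros)).max() == 0.0
        checker = np.indices((16, 16)).sum(axis=0) % 2 == 0
        out = compose_ground_truth(np.full((16, 16), 100.0), checker)
        assert set(np.unique(out)) == {0.0, 100.0}
        assert np.array_equal(out > 0, checker)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_ground_truth(np.zeros((4, 4)), np.zeros((5, 4)))

    def test_zero_mass_outside_annotation_random(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            tex = rng.random((12, 12)) * 255
            ann = rng.random((12, 12)) > 0.5
            out = compose_ground_truth(tex, ann)
            assert np.abs(out[~ann]).max() == 0.0


def test_texture_maps_enhance_their_features(sample96):
    """End-to-end polarity: each filter scores its own feature class above
    the image-wide average."""
    s = sample96
    gray = to_grayscale(s.image)
    wmap = wrinkle_texture_map(gray)
    assert wmap[s.fine_wrinkle_mask].mean() > wmap.mean()
    pmap = pore_texture_map(gray)
    assert pmap[s.fine_pore_mask].mean() > pmap.mean()
    gt = make_ground_truth(s.image, s.coarse_wrinkle_annotation,
                           s.coarse_pore_annotation)
    assert np.abs(gt.wrinkle[~s.coarse_wrinkle_annotation]).max() == 0.0
    assert np.abs(gt.pore[~s.coarse_pore_annotation]).max() == 0.0
    assert gt.pore[s.fine_pore_mask].mean() > 32.0  # pores visible in GT
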