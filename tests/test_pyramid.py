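"""Pyramid geometry: resize conventions, tiling partition, view order."""

import numpy as np
import pytest

from pyrafex.pyramid import (
    ConfigurationError,
    InvalidImageError,
    PyramidConfig,
    as_rgb_image,
    bilinear_resize,
    n_views,
    pyramid_views,
    resize_to_working,
    tile,
    upscale_patch,
)

from conftest import random_rgb


def hand_bilinear(img, out_h, out_w):
    """Per-pixel loop oracle: half-pixel centers, edge clamp."""
    in_h, in_w = img.shape[:2]
    out = np.zeros((out_h, out_w, img.shape[2]))
    for i in range(out_h):
        for j in range(out_w):
            y = min(max((i + 0.5) * in_h / out_h - 0.5, 0.0), in_h - 1.0)
            x = min(max((j + 0.5) * in_w / out_w - 0.5, 0.0), in_w - 1.0)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, in_h - 1), min(x0 + 1, in_w - 1)
            fy, fx = y - y0, x - x0
            out[i, j] = (
                img[y0, x0] * (1 - fy) * (1 - fx)
                + img[y0, x1] * (1 - fy) * fx
                + img[y1, x0] * fy * (1 - fx)
                + img[y1, x1] * fy * fx
            )
    return out


class TestResize:
    def test_identity_is_bit_exact(self):
        img = random_rgb(np.random.default_rng(0), 224, 224)
        out = resize_to_working(img, PyramidConfig())
        assert out.shape == (224, 224, 3)
        np.testing.assert_array_equal(out, img)

    def test_constant_field_is_interpolation_invariant(self):
        img = np.full((448, 448, 3), 0.5)
        out = resize_to_working(img, PyramidConfig())
        np.testing.assert_allclose(out, 0.5, rtol=0, atol=1e-14)

    def test_2x2_upscale_matches_hand_oracle(self):
        img = np.zeros((2, 2, 3))
        img[0, 1] = img[1, 0] = 1.0
        out = bilinear_resize(img, 4, 4)
        np.testing.assert_allclose(out, hand_bilinear(img, 4, 4), atol=1e-14)

    @pytest.mark.parametrize("shape,out_side", [((7, 5), 13), ((30, 40), 8)])
    def test_matches_skimage_independent_oracle(self, shape, out_side):
        from skimage.transform import resize as skresize

        img = random_rgb(np.random.default_rng(3), *shape)
        ours = bilinear_resize(img, out_side, out_side)
        ref = skresize(img, (out_side, out_side), order=1,
                       anti_aliasing=False, mode="edge", preserve_range=True)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_aspect_ratio_not_preserved(self):
        # a vertical edge at mid-width stays at mid-width after stretching
        img = np.zeros((100, 300, 3))
        img[:, 150:] = 1.0
        out = resize_to_working(img, PyramidConfig())
        assert out[:, :100].mean() < 0.01 and out[:, -100:].mean() > 0.99

    def test_rejects_bad_input(self):
        with pytest.raises(InvalidImageError):
            resize_to_working(np.empty((0, 3, 3)), PyramidConfig())
        with pytest.raises(InvalidImageError):
            as_rgb_image(np.full((4, 4), np.nan))
        with pytest.raises(InvalidImageError):
            as_rgb_image(np.full((4, 4), 2.0))

    def test_grayscale_is_channel_replicated(self):
        img = as_rgb_image(np.random.default_rng(1).random((5, 5)))
        assert img.shape == (5, 5, 3)
        np.testing.assert_array_equal(img[..., 0], img[..., 2])


class TestTile:
    @pytest.mark.parametrize("side,count", [(28, 64), (56, 16), (112, 4), (224, 1)])
    def test_grid_counts(self, side, count):
        img = random_rgb(np.random.default_rng(2), 224, 224)
        assert len(tile(img, side)) == count

    def test_full_side_tile_is_identity(self):
        img = random_rgb(np.random.default_rng(2), 224, 224)
        [(addr, patch)] = tile(img, 224)
        assert (addr.row_index, addr.col_index) == (0, 0)
        np.testing.assert_array_equal(patch, img)

    def test_quadrant_values_in_row_major_order(self):
        img = np.zeros((224, 224, 3))
        for q, (r, c) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            img[r * 112 : (r + 1) * 112, c * 112 : (c + 1) * 112] = 0.1 * (q + 1)
        patches = tile(img, 112)
        for q, (addr, patch) in enumerate(patches):
            assert (addr.row_index, addr.col_index) == (q // 2, q % 2)
            np.testing.assert_array_equal(patch, np.full((112, 112, 3), 0.1 * (q + 1)))

    def test_partition_reassembles_bit_exactly(self):
        img = random_rgb(np.random.default_rng(4), 56, 56)
        for side in (7, 14, 28, 56):
            patches = tile(img, side)
            n = 56 // side
            rebuilt = np.concatenate(
                [
                    np.concatenate(
                        [patches[r * n + c][1] for c in range(n)], axis=1
                    )
                    for r in range(n)
                ],
                axis=0,
            )
            np.testing.assert_array_equal(rebuilt, img)

    def test_non_divisor_side_is_configuration_error(self):
        img = random_rgb(np.random.default_rng(5), 224, 224)
        with pytest.raises(ConfigurationError):
            tile(img, 100)


class TestUpscaleAndViews:
    def test_constant_patch_stays_constant(self):
        patch = np.full((28, 28, 3), 0.7)
        out = upscale_patch(patch, PyramidConfig())
        assert out.shape == (224, 224, 3)
        np.testing.assert_allclose(out, 0.7, atol=1e-14)

    def test_working_size_patch_unchanged(self):
        patch = random_rgb(np.random.default_rng(6), 224, 224)
        np.testing.assert_array_equal(upscale_patch(patch, PyramidConfig()), patch)

    def test_default_config_yields_85_views(self):
        img = random_rgb(np.random.default_rng(7), 64, 48)
        views = pyramid_views(img, PyramidConfig())
        assert len(views) == 85 == n_views(PyramidConfig())
        assert all(v.shape == (224, 224, 3) for _, v in views)

    def test_single_scale_no_full_image(self):
        cfg = PyramidConfig(patch_sides=(112,), include_full_image=False)
        img = random_rgb(np.random.default_rng(8), 224, 224)
        assert len(pyramid_views(img, cfg)) == 4

    def test_empty_scales_full_only_equals_resize(self):
        cfg = PyramidConfig(patch_sides=())
        img = random_rgb(np.random.default_rng(9), 100, 80)
        [(addr, view)] = pyramid_views(img, cfg)
        np.testing.assert_array_equal(view, resize_to_working(img, cfg))

    def test_view_order_is_smallest_scale_first(self, small_pyramid):
        img = random_rgb(np.random.default_rng(10), 56, 56)
        addrs = [a for a, _ in pyramid_views(img, small_pyramid)]
        assert [a.scale_side for a in addrs] == [14] * 16 + [28] * 4 + [56]
        assert [(a.row_index, a.col_index) for a in addrs[:4]] == [
            (0, 0), (0, 1), (0, 2), (0, 3)
        ]

    def test_views_deterministic_and_in_range(self, small_pyramid):
        img = random_rgb(np.random.default_rng(11), 37, 91)
        v1 = pyramid_views(img, small_pyramid)
        v2 = pyramid_views(img, small_pyramid)
        for (_, a), (_, b) in zip(v1, v2):
            np.testing.assert_array_equal(a, b)
            assert a.min() >= 0.0 and a.max() <= 1.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            PyramidConfig(patch_sides=(30,))
        with pytest.raises(ConfigurationError):
            PyramidConfig(patch_sides=(112, 56))
        with pytest.raises(ConfigurationError):
            PyramidConfig(working_side=0)
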