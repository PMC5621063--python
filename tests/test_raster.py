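import numpy as np
import pytest

from patchscale import (
    RasterBand,
    Scene,
    block_aggregate,
    interpolate_upscale,
    residual_field,
)


class TestRasterBand:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RasterBand(np.zeros((2, 2)), np.zeros((3, 3), dtype=bool))

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            RasterBand(np.zeros((2, 2)), band="ultraviolet")

    def test_reflectance_range_guard(self):
        band = RasterBand(np.array([[0.5, 1.5]]), band="red")
        with pytest.raises(ValueError):
            band.validate_range()
        RasterBand(np.array([[250.0, 330.0]]), band="thermal").validate_range()

    def test_scene_requires_common_grid(self):
        a = RasterBand(np.zeros((4, 4)), pixel_size=30, band="red")
        b = RasterBand(np.zeros((8, 8)), pixel_size=30, band="nir")
        with pytest.raises(ValueError):
            Scene({"red": a, "nir": b})


class TestBlockAggregate:
    def test_mean_of_block(self):
        band = RasterBand(np.array([[1.0, 3.0], [5.0, 7.0]]), pixel_size=15)
        out = block_aggregate(band, 2)
        np.testing.assert_allclose(out.values, [[4.0]])
        assert out.pixel_size == 30

    def test_constant_preserved(self):
        out = block_aggregate(RasterBand(np.full((8, 8), 0.37)), 4)
        np.testing.assert_allclose(out.values, 0.37)

    def test_valid_fraction_threshold(self):
        mask = np.array([[True, True], [True, False]])
        band = RasterBand(np.ones((2, 2)), mask)
        assert block_aggregate(band, 2, min_valid_fraction=0.5).mask.all()
        assert not block_aggregate(band, 2, min_valid_fraction=0.25).mask.any()

    def test_partial_mask_uses_valid_mean(self):
        band = RasterBand(np.array([[2.0, 4.0], [6.0, 100.0]]),
                          np.array([[False, False], [False, True]]))
        out = block_aggregate(band, 2, min_valid_fraction=0.5)
        assert out.values[0, 0] == pytest.approx(4.0)

    def test_global_mean_preserved(self, rng):
        vals = rng.random((12, 12))
        out = block_aggregate(RasterBand(vals), 3)
        assert out.values.mean() == pytest.approx(vals.mean())

    def test_non_divisible_crops_with_warning(self):
        band = RasterBand(np.arange(25, dtype=float).reshape(5, 5))
        with pytest.warns(UserWarning):
            out = block_aggregate(band, 2)
        assert out.shape == (2, 2)

    @pytest.mark.parametrize("factor", [1, 0, 2.5])
    def test_bad_factor(self, factor):
        with pytest.raises(ValueError):
            block_aggregate(RasterBand(np.zeros((4, 4))), factor)


class TestInterpolateUpscale:
    @pytest.mark.parametrize("kernel", ["nearest", "bilinear", "bicubic"])
    @pytest.mark.parametrize("s", [2, 3])
    def test_constant_stays_constant(self, kernel, s):
        out = interpolate_upscale(RasterBand(np.full((5, 4), 0.3)), s, kernel)
        assert out.shape == (5 * s, 4 * s)
        np.testing.assert_allclose(out.values, 0.3)

    def test_nearest_replicates_blocks(self):
        band = RasterBand(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = interpolate_upscale(band, 2, "nearest")
        np.testing.assert_array_equal(
            out.values, [[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]]
        )

    @pytest.mark.parametrize("s", [2, 4])
    def test_nearest_then_aggregate_is_identity(self, checker_band, s):
        back = block_aggregate(interpolate_upscale(checker_band, s, "nearest"), s)
        np.testing.assert_array_equal(back.values, checker_band.values)

    def test_pixel_size_divided(self, checker_band):
        assert interpolate_upscale(checker_band, 2).pixel_size == 15.0

    def test_mask_propagates_over_kernel_footprint(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[3, 3] = True
        band = RasterBand(np.ones((6, 6)), mask)
        out = interpolate_upscale(band, 2, "bicubic")
        # bicubic footprint spans 2 input cells each way
        assert out.mask[6:8, 6:8].all()
        assert out.mask[2:10, 2:10].all()
        assert not out.mask[0, 0]

    def test_unknown_kernel_lists_valid(self):
        with pytest.raises(ValueError, match="bilinear"):
            interpolate_upscale(RasterBand(np.ones((2, 2))), 2, "lanczos")


class TestResidualField:
    def test_self_difference_is_zero(self, checker_band):
        hr = interpolate_upscale(checker_band, 2, "bilinear")
        res = residual_field(hr, checker_band, 2, "bilinear")
        np.testing.assert_allclose(res.values, 0.0, atol=1e-12)

    def test_single_cell_delta(self, checker_band):
        hr = interpolate_upscale(checker_band, 2, "nearest")
        hr.values[5, 5] += 0.1
        res = residual_field(hr, checker_band, 2, "nearest")
        expect = np.zeros(hr.shape)
        expect[5, 5] = 0.1
        np.testing.assert_allclose(res.values, expect, atol=1e-12)

    def test_reconstruction_identity(self, checker_band, rng):
        hr = RasterBand(rng.random((16, 16)), None, 15.0, "red")
        res = residual_field(hr, checker_band, 2, "bicubic")
        rebuilt = res.values + interpolate_upscale(checker_band, 2, "bicubic").values
        np.testing.assert_allclose(rebuilt, hr.values, atol=1e-12)

    def test_shape_mismatch_reports_shapes(self):
        lr = RasterBand(np.ones((4, 4)))
        hr = RasterBand(np.ones((6, 6)))
        with pytest.raises(ValueError, match=r"\(6, 6\)"):
            residual_field(hr, lr, 2)

    def test_band_mismatch(self):
        lr = RasterBand(np.ones((4, 4)), band="red")
        hr = RasterBand(np.ones((8, 8)), band="nir")
        with pytest.raises(ValueError, match="band"):
            residual_field(hr, lr, 2)
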