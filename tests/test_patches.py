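import numpy as np
import pytest

from patchscale import (
    CoupledDictionary,
    RasterBand,
    assemble_patches,
    build_coupled_dictionary,
    extract_patches,
    interpolate_upscale,
)


def _band(values, band="red", mask=None):
    return RasterBand(np.asarray(values, dtype=float), mask, 30.0, band)


class TestExtract:
    def test_non_overlapping_tiling(self):
        band = _band(np.arange(16).reshape(4, 4))
        ps = extract_patches(band, 2, 2)
        assert ps.n_patches == 4
        np.testing.assert_array_equal(ps.vectors[:, 0], [0, 1, 4, 5])
        assert ps.origin_grid[0] == (0, 0)

    def test_coverage_completing_origins(self):
        ps = extract_patches(_band(np.zeros((5, 5))), 2, 2)
        # origins {0, 2, 3} per axis: right/bottom-aligned extras cover all cells
        assert ps.n_patches == 9
        assert {o[0] for o in ps.origin_grid} == {0, 2, 3}

    def test_drop_masked_omits_exactly_touching_patches(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        ps = extract_patches(_band(np.zeros((4, 4)), mask=mask), 2, 2)
        assert ps.n_patches == 3
        assert (0, 0) not in ps.origin_grid

    def test_patch_larger_than_image(self):
        with pytest.raises(ValueError):
            extract_patches(_band(np.zeros((3, 3))), 4, 1)


class TestAssemble:
    def test_partition_round_trip(self, rng):
        band = _band(rng.random((6, 6)))
        back = assemble_patches(extract_patches(band, 3, 3), (6, 6))
        np.testing.assert_array_equal(back.values, band.values)
        assert not back.mask.any()

    def test_overlapping_round_trip(self, rng):
        band = _band(rng.random((7, 5)))
        back = assemble_patches(extract_patches(band, 3, 1), (7, 5))
        np.testing.assert_allclose(back.values, band.values, atol=1e-12)

    def test_disagreeing_patches_average(self):
        ps = extract_patches(_band(np.zeros((3, 2))), 2, 1)
        # two patches overlap on the middle row; make them disagree by 0.2
        ps.vectors[:, 0] = 0.0
        ps.vectors[:, 1] = 0.0
        ps.vectors[0:2, 1] = 0.2  # patch at (1,0): its top row is the shared cells
        out = assemble_patches(ps, (3, 2))
        np.testing.assert_allclose(out.values[1], 0.1)

    def test_uncovered_cells_masked(self):
        band = _band(np.zeros((4, 4)))
        ps = extract_patches(band, 2, 2)
        ps.origin_grid = ps.origin_grid[:1]
        ps.vectors = ps.vectors[:, :1]
        out = assemble_patches(ps, (4, 4))
        assert not out.mask[:2, :2].any()
        assert out.mask[2:, 2:].all()

    def test_geometry_mismatch(self, rng):
        ps = extract_patches(_band(rng.random((4, 4))), 2, 2)
        with pytest.raises(ValueError):
            assemble_patches(ps, (5, 5))


class TestCoupledDictionary:
    def test_shapes_from_tiling(self, rng):
        lr = _band(rng.random((8, 8)))
        hr = _band(rng.random((16, 16)))
        d = build_coupled_dictionary([(lr, hr)], 2, patch_edge=2, stride=2)
        assert d.D_l.shape == (4, 16)
        assert d.D_h.shape == (16, 16)
        np.testing.assert_allclose(np.linalg.norm(d.D_l, axis=0), 1.0, atol=1e-12)

    def test_zero_residual_when_hr_is_interpolated_lr(self, rng):
        lr = _band(rng.random((8, 8)))
        hr = interpolate_upscale(lr, 2, "bicubic")
        d = build_coupled_dictionary([(lr, hr)], 2, patch_edge=2, stride=2, kernel="bicubic")
        np.testing.assert_allclose(d.D_h, 0.0, atol=1e-12)

    def test_three_pairs_patch_count_bookkeeping(self, rng):
        # three coincident pairs contributing 2922 patch pairs each make an
        # 8766-atom dictionary (2 x 1461 coarse grid, p=1, stride 1)
        pairs = []
        for k in range(3):
            lr = _band(np.random.default_rng(k).random((2, 1461)))
            hr = _band(np.random.default_rng(100 + k).random((4, 2922)))
            pairs.append((lr, hr))
        d = build_coupled_dictionary(pairs, 2, patch_edge=1, stride=1)
        assert d.n_atoms == 3 * 2922 == 8766

    def test_column_correspondence_under_pair_permutation(self, rng):
        lr1, hr1 = _band(rng.random((4, 4))), _band(rng.random((8, 8)))
        lr2, hr2 = _band(rng.random((4, 4))), _band(rng.random((8, 8)))
        d12 = build_coupled_dictionary([(lr1, hr1), (lr2, hr2)], 2, 2, 2)
        d21 = build_coupled_dictionary([(lr2, hr2), (lr1, hr1)], 2, 2, 2)
        half = d12.n_atoms // 2
        np.testing.assert_array_equal(d12.D_l[:, :half], d21.D_l[:, half:])
        np.testing.assert_array_equal(d12.D_h[:, :half], d21.D_h[:, half:])

    def test_geometric_correspondence_painted_coordinates(self):
        # paint the HR image with its row-major cell index; the HR patch at
        # origin (s*r, s*c) must contain exactly the block covering the LR
        # patch's ground footprint
        lr = _band(np.arange(1.0, 17.0).reshape(4, 4))
        hr_vals = np.arange(64, dtype=float).reshape(8, 8)
        hr = _band(hr_vals)
        d = build_coupled_dictionary([(lr, hr)], 2, patch_edge=2, stride=2,
                                     residual_mode=False)
        # LR origin (2, 0) is atom 2 in row-major origin order
        expected = hr_vals[4:8, 0:4].ravel()
        norm = d.atom_norms[2]
        np.testing.assert_allclose(d.D_h[:, 2] * norm, expected)

    def test_masked_pairs_dropped(self, rng):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        lr = _band(rng.random((4, 4)), mask=mask)
        hr = _band(rng.random((8, 8)))
        # nearest kernel: the mask contaminates exactly the matching HR block
        d = build_coupled_dictionary([(lr, hr)], 2, 2, 2, kernel="nearest")
        assert d.n_atoms == 3

    def test_mixed_bands_rejected(self, rng):
        lr = _band(rng.random((4, 4)), band="red")
        hr = _band(rng.random((8, 8)), band="nir")
        with pytest.raises(ValueError, match="band"):
            build_coupled_dictionary([(lr, hr)], 2, 2, 2)

    def test_empty_after_filtering_advises(self):
        lr = _band(np.ones((4, 4)), mask=np.ones((4, 4), dtype=bool))
        hr = _band(np.ones((8, 8)))
        with pytest.raises(ValueError, match="stride"):
            build_coupled_dictionary([(lr, hr)], 2, 2, 2)

    def test_zero_norm_lr_patches_never_enter(self):
        lr = _band(np.zeros((4, 4)))
        lr.values[2:, 2:] = 1.0
        hr = _band(np.random.default_rng(0).random((8, 8)))
        d = build_coupled_dictionary([(lr, hr)], 2, 2, 2)
        assert d.n_atoms == 1  # the three all-zero LR tiles are excluded
        np.testing.assert_allclose(np.linalg.norm(d.D_l, axis=0), 1.0, atol=1e-12)

    def test_save_load_round_trip(self, tmp_path, rng):
        lr = _band(rng.random((4, 4)))
        hr = _band(rng.random((8, 8)))
        d = build_coupled_dictionary([(lr, hr)], 2, 2, 2)
        path = tmp_path / "dict.npz"
        d.save(path)
        back = CoupledDictionary.load(path)
        np.testing.assert_array_equal(back.D_l, d.D_l)
        np.testing.assert_array_equal(back.D_h, d.D_h)
        assert (back.s, back.patch_edge, back.band) == (2, 2, "red")
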