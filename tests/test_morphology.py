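"""Binary morphology: FFT back-end vs brute-force oracles and algebra laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmorphseg import (BinaryMask, StructuringElement, dilate, erode,
                        open_mask, close_mask, make_cube_se, make_prism_se,
                        make_sphere_se, use_backend)
from ctmorphseg.morphology import binary_convolution

from oracles import (minkowski_dilate, duality_erode, brute_open, brute_close,
                     random_mask, random_se)


def mask_of(grid):
    return BinaryMask(np.asarray(grid, dtype=bool))


class TestDilate:
    def test_point_dilates_to_se_footprint(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        out = dilate(mask_of(m), make_cube_se(3))
        expected = np.zeros((9, 9, 9), bool)
        expected[3:6, 3:6, 3:6] = True
        assert np.array_equal(out.grid, expected)

    def test_empty_mask_stays_empty(self):
        out = dilate(mask_of(np.zeros((8, 8, 8), bool)), make_cube_se(5))
        assert not out.grid.any()

    def test_se_larger_than_mask_rejected(self):
        with pytest.raises(ValueError, match="exceeds mask extent"):
            dilate(mask_of(np.zeros((3, 3, 3), bool)), make_cube_se(5))

    def test_matches_minkowski_oracle_on_random_instances(self, rng):
        for _ in range(30):
            m = random_mask(rng, tuple(rng.integers(6, 17, 3)))
            se = random_se(rng, max_extent=5)
            out = dilate(mask_of(m), StructuringElement(se))
            assert np.array_equal(out.grid, minkowski_dilate(m, se))


class TestErode:
    def test_all_true_preserved_at_border(self):
        m = mask_of(np.ones((8, 8, 8), bool))
        assert erode(m, make_cube_se(3)).grid.all()

    def test_single_voxel_vanishes(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True
        assert not erode(mask_of(m), make_cube_se(3)).grid.any()

    def test_matches_duality_oracle_on_random_instances(self, rng):
        for _ in range(30):
            m = random_mask(rng, tuple(rng.integers(6, 17, 3)), density=0.7)
            se = random_se(rng, max_extent=5)
            out = erode(mask_of(m), StructuringElement(se))
            assert np.array_equal(out.grid, duality_erode(m, se))


class TestOpenClose:
    def test_open_and_close_match_oracles(self, rng):
        for _ in range(15):
            m = random_mask(rng, (12, 12, 12), density=0.4)
            se = random_se(rng, max_extent=5)
            assert np.array_equal(
                open_mask(mask_of(m), StructuringElement(se)).grid,
                brute_open(m, se))
            assert np.array_equal(
                close_mask(mask_of(m), StructuringElement(se)).grid,
                brute_close(m, se))

    def test_idempotence_with_symmetric_se(self, rng):
        se = make_cube_se(3)
        for _ in range(25):
            m = mask_of(random_mask(rng, (16, 16, 16)))
            once, twice = open_mask(m, se), open_mask(open_mask(m, se), se)
            assert once == twice
            once, twice = close_mask(m, se), close_mask(close_mask(m, se), se)
            assert once == twice

    def test_open_removes_isolated_voxel(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        m[0, 0, 0] = True
        out = open_mask(mask_of(m), make_cube_se(3))
        assert not out.grid[0, 0, 0]
        assert out.grid[3, 3, 3]

    def test_close_bridges_one_voxel_gap_between_cubes(self):
        m = np.zeros((13, 11, 11), bool)
        m[1:6, 3:8, 3:8] = True    # 5^3 cube
        m[7:12, 3:8, 3:8] = True   # second cube, 1-voxel gap at x=6
        out = close_mask(mask_of(m), make_cube_se(3))
        assert np.array_equal(out.grid, brute_close(m, make_cube_se(3).grid))
        assert out.grid[6, 4:7, 4:7].all()


class TestAlgebraicLaws:
    def test_duality_for_symmetric_se(self, rng):
        se = make_cube_se(3)
        for _ in range(20):
            m = mask_of(random_mask(rng, (14, 14, 14), density=0.5))
            assert erode(m, se) == dilate(m.complement(), se).complement()

    def test_extensivity_and_antiextensivity(self, rng):
        # se containing its origin: dilation grows, erosion shrinks
        for _ in range(20):
            se_grid = random_se(rng, max_extent=5)
            se_grid[tuple(s // 2 for s in se_grid.shape)] = True
            se = StructuringElement(se_grid)
            m = mask_of(random_mask(rng, (14, 14, 14)))
            assert (m.grid <= dilate(m, se).grid).all()
            assert (erode(m, se).grid <= m.grid).all()

    def test_monotonicity(self, rng):
        for _ in range(20):
            se = StructuringElement(random_se(rng, max_extent=5))
            m1 = random_mask(rng, (14, 14, 14))
            m2 = m1 | random_mask(rng, (14, 14, 14))
            d1 = dilate(mask_of(m1), se).grid
            d2 = dilate(mask_of(m2), se).grid
            assert (d1 <= d2).all()

    def test_fft_convolution_values_near_integers(self, rng):
        for _ in range(20):
            m = random_mask(rng, tuple(rng.integers(8, 33, 3)))
            se = StructuringElement(random_se(rng, max_extent=9))
            conv = binary_convolution(m, se)
            assert np.abs(conv - np.rint(conv)).max() < 1e-3


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 31 - 1))
def test_backends_agree_bit_exactly(seed):
    rng = np.random.default_rng(seed)
    m = mask_of(random_mask(rng, tuple(rng.integers(8, 21, 3))))
    se = StructuringElement(random_se(rng, max_extent=7))
    for op in (dilate, erode, open_mask, close_mask):
        with use_backend("fft"):
            a = op(m, se)
        with use_backend("direct"):
            b = op(m, se)
        assert a == b


class TestSphereSE:
    def test_10mm_sphere_at_2mm_spacing(self):
        se = make_sphere_se(10, (2, 2, 2))
        assert se.shape == (5, 5, 5)
        assert se.grid[2, 2, 2]
        assert not se.grid[0, 0, 0]

    def test_subvoxel_diameter_gives_single_voxel(self):
        se = make_sphere_se(0.5, (1, 1, 1))
        assert se.shape == (1, 1, 1) and se.grid.all()

    def test_anisotropic_spacing_shapes_ellipsoid(self):
        se = make_sphere_se(6, (1, 1, 3))
        assert se.shape == (7, 7, 3)
        # voxel offsets must satisfy the physical-mm inequality exactly
        h = np.array([3, 3, 1])
        for idx in np.ndindex(*se.shape):
            v = (np.array(idx) - h) * np.array([1, 1, 3])
            assert se.grid[idx] == ((v ** 2).sum() <= 9.0)

    def test_symmetric(self):
        assert make_sphere_se(17, (1.5, 2, 0.8)).is_symmetric

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_sphere_se(0, (1, 1, 1))
        with pytest.raises(ValueError):
            make_sphere_se(5, (1, -1, 1))


class TestPrismSE:
    def test_requested_odd_extent_kept(self):
        assert make_prism_se((1, 5, 1)).shape == (1, 5, 1)
        assert make_prism_se((1, 5, 1)).grid.all()

    def test_even_extent_promoted_to_odd(self):
        assert make_prism_se((1, 4, 1)).shape == (1, 5, 1)

    def test_table_puncture_extent_at_2mm_spacing(self):
        # 10 mm prism at d = 2 mm pixel spacing spans 5 voxels along y
        d = 2.0
        extent = int(np.ceil(10 / d))
        assert make_prism_se((1, extent, 1)).shape == (1, 5, 1)

    def test_zero_extent_rejected(self):
        with pytest.raises(ValueError):
            make_prism_se((1, 0, 1))
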