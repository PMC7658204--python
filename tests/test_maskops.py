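"""Connected-component operations vs flood-fill and geodesic oracles."""

import numpy as np
import pytest

from ctmorphseg import (BinaryMask, ComponentCountError, fill_holes_axial,
                        label_components, largest_components,
                        reconstruct_from_seeds, remove_boundary_connected)

from oracles import flood_fill_components, geodesic_reconstruct, random_mask


def mask_of(grid):
    return BinaryMask(np.asarray(grid, dtype=bool))


class TestLabelComponents:
    def test_opposite_corners_are_two_singletons(self):
        g = np.zeros((4, 4, 4), bool)
        g[0, 0, 0] = g[3, 3, 3] = True
        lab = label_components(mask_of(g))
        assert lab.n_components == 2
        assert list(lab.sizes) == [1, 1]

    def test_diagonal_contact_depends_on_connectivity(self):
        g = np.zeros((4, 4, 4), bool)
        g[1, 1, 1] = g[2, 2, 2] = True
        assert label_components(mask_of(g), 26).n_components == 1
        assert label_components(mask_of(g), 6).n_components == 2

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError, match="connectivity"):
            label_components(mask_of(np.zeros((3, 3, 3), bool)), 8)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_sizes_match_flood_fill_oracle(self, rng, connectivity):
        for _ in range(10):
            g = random_mask(rng, (9, 9, 9), density=0.35)
            lab = label_components(mask_of(g), connectivity)
            _, oracle_sizes = flood_fill_components(g, connectivity)
            assert sorted(lab.sizes, reverse=True) == \
                sorted(oracle_sizes, reverse=True)
            # exact partition of the foreground
            assert np.array_equal(lab.labels > 0, g)

    def test_sizes_invariant_under_axis_permutation(self, rng):
        g = random_mask(rng, (7, 8, 9), density=0.3)
        base = sorted(label_components(mask_of(g)).sizes)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            permuted = label_components(mask_of(np.transpose(g, perm)))
            assert sorted(permuted.sizes) == base


class TestLargestComponents:
    @staticmethod
    def _three_cubes():
        g = np.zeros((14, 8, 8), bool)
        g[0:3, 0:3, 0:3] = True     # 27 voxels
        g[5:7, 5:7, 5:7] = True     # 8 voxels
        g[12, 7, 7] = True          # 1 voxel
        return g

    def test_keeps_k_largest(self):
        g = self._three_cubes()
        out = largest_components(mask_of(g), k=2)
        expected = g.copy()
        expected[12, 7, 7] = False
        assert np.array_equal(out.grid, expected)

    def test_identity_on_single_component(self):
        g = np.zeros((5, 5, 5), bool)
        g[1:4, 1:4, 1:4] = True
        assert largest_components(mask_of(g), k=1) == mask_of(g)

    def test_equal_sizes_tie_broken_by_linear_index(self):
        g = np.zeros((9, 3, 3), bool)
        g[0, 0, 0] = g[8, 2, 2] = True
        out = largest_components(mask_of(g), k=1)
        assert out.grid[0, 0, 0] and not out.grid[8, 2, 2]

    def test_too_few_components_reported(self):
        g = self._three_cubes()
        with pytest.raises(ComponentCountError) as err:
            largest_components(mask_of(g), k=5)
        assert err.value.found == 3 and err.value.requested == 5

    def test_monotone_in_k_and_subset_of_input(self, rng):
        g = random_mask(rng, (10, 10, 10), density=0.2)
        m = mask_of(g)
        n = label_components(m).n_components
        previous = np.zeros_like(g)
        for k in range(1, n + 1):
            out = largest_components(m, k).grid
            assert (previous <= out).all() and (out <= g).all()
            previous = out


class TestRemoveBoundaryConnected:
    def test_frame_removed_interior_blob_kept(self):
        g = np.zeros((9, 9, 5), bool)
        g[:, 0, 2] = g[:, -1, 2] = g[0, :, 2] = g[-1, :, 2] = True  # frame
        g[4, 4, 2] = True
        out = remove_boundary_connected(mask_of(g))
        assert out.count() == 1 and out.grid[4, 4, 2]

    def test_touching_z_face_only_is_kept(self):
        g = np.zeros((9, 9, 5), bool)
        g[3:6, 3:6, 0:2] = True  # rests on the first z-slice, interior in-plane
        out = remove_boundary_connected(mask_of(g))
        assert out == mask_of(g)

    def test_phantom_exterior_and_table_removed_lungs_kept(self, phantom):
        from ctmorphseg import close_mask, make_prism_se
        f_tau = BinaryMask(phantom.ct.hu <= -150, phantom.ct.spacing)
        closed = close_mask(f_tau, make_prism_se((1, 5, 1)))
        out = remove_boundary_connected(closed)
        assert not (out.grid & phantom.regions["exterior_air"]).any()
        assert not (out.grid & phantom.regions["table_interior"]).any()
        assert (out.grid & phantom.regions["lungs"]).sum() \
            > 0.99 * phantom.regions["lungs"].sum()


class TestFillHolesAxial:
    def test_ring_becomes_solid_square(self):
        g = np.zeros((9, 9, 3), bool)
        g[2:7, 2:7, 1] = True
        g[3:6, 3:6, 1] = False
        out = fill_holes_axial(mask_of(g))
        assert out.grid[2:7, 2:7, 1].all()
        assert out.count() == 25

    def test_c_shape_open_to_border_unchanged(self):
        g = np.zeros((9, 9, 3), bool)
        g[2:7, 2:7, 1] = True
        g[3:6, 3:6, 1] = False
        g[4, 2, 1] = False  # breach the ring wall
        g[4, 3:6, 1] = False  # channel joining hole to the breach
        out = fill_holes_axial(mask_of(g))
        assert out == mask_of(g)

    def test_solid_mask_unchanged_and_idempotent_extensive(self, rng):
        solid = np.ones((5, 5, 5), bool)
        assert fill_holes_axial(mask_of(solid)) == mask_of(solid)
        g = random_mask(rng, (12, 12, 6), density=0.45)
        once = fill_holes_axial(mask_of(g))
        assert (g <= once.grid).all()
        assert fill_holes_axial(once) == once


class TestReconstructFromSeeds:
    def test_seed_selects_whole_component(self):
        g = np.zeros((12, 6, 6), bool)
        g[1:4, 1:4, 1:4] = True
        g[8:11, 1:4, 1:4] = True
        seed = np.zeros_like(g)
        seed[2, 2, 2] = True
        out = reconstruct_from_seeds(mask_of(g), mask_of(seed))
        expected = np.zeros_like(g)
        expected[1:4, 1:4, 1:4] = True
        assert np.array_equal(out.grid, expected)

    def test_empty_seeds_give_empty_mask(self, rng):
        g = random_mask(rng, (8, 8, 8))
        out = reconstruct_from_seeds(mask_of(g),
                                     mask_of(np.zeros_like(g)))
        assert not out.grid.any()

    def test_matches_iterated_conditional_dilation(self, rng):
        for _ in range(10):
            ref = random_mask(rng, (8, 8, 8), density=0.35)
            seeds = random_mask(rng, (8, 8, 8), density=0.05)
            out = reconstruct_from_seeds(mask_of(ref), mask_of(seeds))
            assert np.array_equal(out.grid, geodesic_reconstruct(ref, seeds))

    def test_self_reconstruction_is_identity(self, rng):
        g = random_mask(rng, (8, 8, 8))
        assert reconstruct_from_seeds(mask_of(g), mask_of(g)) == mask_of(g)
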