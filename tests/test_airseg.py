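import numpy as np
import pytest

from _oracles import bfs_flood_fill
from lungmorph import airseg
from lungmorph.gridio import Mask, VoxelGrid

SP = (10.0, 10.0, 10.0)


class TestRegionGrow:
    def test_uniform_grid_fills_everything(self):
        grid = VoxelGrid(np.full((5, 5, 5), 4000, dtype=np.uint16), SP)
        mask = airseg.region_grow(grid, airseg.SegmentationConfig(seed=(2, 2, 2)))
        assert mask.count() == 125

    def test_tissue_wall_blocks_growth(self):
        values = np.full((5, 5, 9), 5000, dtype=np.uint16)
        values[:, :, 4] = 30000  # wall between two chambers
        grid = VoxelGrid(values, SP)
        mask = airseg.region_grow(grid, airseg.SegmentationConfig(seed=(2, 2, 1)))
        assert mask.values[:, :, :4].all()
        assert not mask.values[:, :, 4:].any()

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bfs_oracle_random(self, rng, connectivity):
        for _ in range(50):
            values = rng.integers(0, 6, size=(20, 20, 20)).astype(np.uint16) * 1000
            seed = tuple(rng.integers(0, 20, size=3))
            tol = int(rng.integers(500, 3000))
            grid = VoxelGrid(values, SP)
            cfg = airseg.SegmentationConfig(
                seed=seed, tolerance=tol, connectivity=connectivity
            )
            got = airseg.region_grow(grid, cfg)
            want = bfs_flood_fill(values, seed, tol, connectivity)
            np.testing.assert_array_equal(got.values, want)

    def test_matches_bfs_oracle_exhaustive_6cube(self, rng):
        for _ in range(2):
            values = rng.integers(0, 4, size=(6, 6, 6)).astype(np.uint16) * 1500
            grid = VoxelGrid(values, SP)
            for seed in np.ndindex(6, 6, 6):
                cfg = airseg.SegmentationConfig(seed=seed, tolerance=1500)
                got = airseg.region_grow(grid, cfg)
                want = bfs_flood_fill(values, seed, 1500, 6)
                np.testing.assert_array_equal(got.values, want)

    def test_mask_monotone_in_tolerance(self, rng):
        values = rng.integers(0, 65536, size=(12, 12, 12), dtype=np.uint16)
        grid = VoxelGrid(values, SP)
        prev = None
        for tol in (500, 2000, 8000, 30000):
            mask = airseg.region_grow(
                grid, airseg.SegmentationConfig(seed=(6, 6, 6), tolerance=tol)
            )
            if prev is not None:
                assert (prev.values & ~mask.values).sum() == 0
            prev = mask

    def test_leak_guard_raises_distinct_error(self):
        grid = VoxelGrid(np.full((10, 10, 10), 4000, dtype=np.uint16), SP)
        cfg = airseg.SegmentationConfig(seed=(0, 0, 0), max_voxels=100)
        with pytest.raises(airseg.RegionLeakError):
            airseg.region_grow(grid, cfg)

    def test_seed_outside_volume(self):
        grid = VoxelGrid(np.zeros((4, 4, 4), dtype=np.uint16), SP)
        with pytest.raises(ValueError):
            airseg.region_grow(grid, airseg.SegmentationConfig(seed=(4, 0, 0)))


class TestExtendRoi:
    def test_full_component_is_fixed_point(self):
        values = np.full((5, 5, 9), 5000, dtype=np.uint16)
        values[:, :, 4] = 30000
        grid = VoxelGrid(values, SP)
        cfg = airseg.SegmentationConfig(seed=(2, 2, 1))
        base = airseg.region_grow(grid, cfg)
        extended = airseg.extend_roi(grid, base, cfg)
        np.testing.assert_array_equal(extended.values, base.values)

    def test_extends_from_trachea_to_entire_lumen(self, small_phantom):
        truth = small_phantom
        cfg = airseg.SegmentationConfig(seed=truth.trachea_seed)
        # base: just the seed voxel
        base = np.zeros(truth.gray.shape, dtype=bool)
        base[truth.trachea_seed] = True
        extended = airseg.extend_roi(grid=truth.gray, base=Mask(base, truth.gray.spacing), cfg=cfg)
        reference = airseg.region_grow(truth.gray, cfg)
        np.testing.assert_array_equal(extended.values, reference.values)

    def test_empty_base_rejected(self):
        grid = VoxelGrid(np.zeros((4, 4, 4), dtype=np.uint16), SP)
        empty = Mask(np.zeros((4, 4, 4), dtype=bool), SP)
        with pytest.raises(ValueError):
            airseg.extend_roi(grid, empty, airseg.SegmentationConfig(seed=(0, 0, 0)))


class TestExcludeExternalAir:
    def test_keeps_only_seed_component(self):
        values = np.zeros((3, 3, 11), dtype=bool)
        values[1, 1, 0:4] = True  # largest
        values[1, 1, 6:8] = True
        values[1, 1, 10] = True
        mask = Mask(values, SP)
        kept = airseg.exclude_external_air(mask, (1, 1, 1))
        assert kept.count() == 4
        assert kept.values[1, 1, 0:4].all()

    def test_single_component_identity(self):
        values = np.zeros((3, 3, 3), dtype=bool)
        values[1] = True
        kept = airseg.exclude_external_air(Mask(values, SP), (1, 1, 1))
        np.testing.assert_array_equal(kept.values, values)

    def test_seed_outside_mask_rejected(self):
        mask = Mask(np.zeros((3, 3, 3), dtype=bool), SP)
        with pytest.raises(ValueError):
            airseg.exclude_external_air(mask, (0, 0, 0))


class TestSplitTreeTerminal:
    def test_truth_mask_split_is_exact(self, small_phantom):
        truth = small_phantom
        entire = Mask(
            truth.tree_mask.values | truth.terminal_mask.values, truth.gray.spacing
        )
        tree, terminal = airseg.split_tree_terminal(entire, truth.tree_mask)
        np.testing.assert_array_equal(terminal.values, truth.terminal_mask.values)
        np.testing.assert_array_equal(tree.values, truth.tree_mask.values)

    def test_boundary_split_disconnects(self):
        # a straight 1D lumen: boundary voxel in the middle separates
        values = np.zeros((3, 3, 11), dtype=bool)
        values[1, 1, :] = True
        entire = Mask(values, SP)
        boundary = np.zeros_like(values)
        boundary[1, 1, 5] = True
        tree, terminal = airseg.split_tree_terminal(entire, boundary, seed=(1, 1, 0))
        assert tree.values[1, 1, :6].all() and not tree.values[1, 1, 6:].any()
        assert terminal.values[1, 1, 6:].all()

    def test_non_disconnecting_boundary_reported(self):
        values = np.ones((3, 3, 3), dtype=bool)
        boundary = np.zeros_like(values)
        boundary[1, 1, 1] = True
        with pytest.raises(ValueError, match="disconnect"):
            airseg.split_tree_terminal(Mask(values, SP), boundary, seed=(0, 0, 0))

    def test_empty_boundary_rejected(self):
        values = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            airseg.split_tree_terminal(
                Mask(values, SP), np.zeros_like(values), seed=(0, 0, 0)
            )

    def test_tree_not_subset_rejected(self):
        entire = Mask(np.zeros((3, 3, 3), dtype=bool), SP)
        tree = Mask(np.ones((3, 3, 3), dtype=bool), SP)
        with pytest.raises(ValueError, match="contained"):
            airseg.split_tree_terminal(entire, tree)


class TestLungOutline:
    def test_solid_phantom_zero_closing_is_tissue_component(self):
        values = np.full((8, 8, 8), 1000, dtype=np.uint16)
        values[2:6, 2:6, 2:6] = 30000  # solid block, no internal air
        grid = VoxelGrid(values, SP)
        mask = airseg.segment_lung_outline(grid, (20000, 65535), (3, 3, 3))
        want = values == 30000
        np.testing.assert_array_equal(mask.values, want)

    def test_internal_air_is_filled(self):
        values = np.full((10, 10, 10), 1000, dtype=np.uint16)
        values[2:8, 2:8, 2:8] = 30000
        values[4:6, 4:6, 4:6] = 5000  # enclosed air pocket
        grid = VoxelGrid(values, SP)
        mask = airseg.segment_lung_outline(grid, (20000, 65535), (2, 2, 2))
        assert mask.values[5, 5, 5]
        assert mask.count() == 6 * 6 * 6

    def test_background_seed_rejected(self):
        grid = VoxelGrid(np.full((4, 4, 4), 1000, dtype=np.uint16), SP)
        with pytest.raises(ValueError):
            airseg.segment_lung_outline(grid, (20000, 65535), (0, 0, 0))
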