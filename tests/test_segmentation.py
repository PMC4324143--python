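"""Unit tests for the segmentation chain."""

import numpy as np
import pytest

from wallvol.grid import VoxelGrid
from wallvol.segmentation import (
    CellMeasurement,
    SegmentationParams,
    close_cell,
    denoise_objects,
    flag_dead,
    label_and_filter,
    clip_to_roi,
    segment_cells,
    threshold_percent_intensity,
)
from wallvol.synthetic import (
    CellSpec,
    GridSpec,
    NoiseSpec,
    OpticsSpec,
    rasterize_cell,
    simulate_stack,
)

NOISELESS = SegmentationParams(noise_filter="none", min_object_volume_um3=5.0)


class TestThreshold:
    def test_constant_grid_empty_mask_with_warning(self, grid_factory):
        grid = grid_factory(np.zeros((4, 4, 4)))
        with pytest.warns(UserWarning, match="constant"):
            mask = threshold_percent_intensity(grid, 3.0)
        assert not mask.any()

    def test_binary_grid_selects_high_values(self, grid_factory):
        values = np.zeros((4, 4, 4))
        values[1, 2, 3] = 100.0
        values[2, 1, 0] = 100.0
        mask = threshold_percent_intensity(grid_factory(values), 3.0)
        assert mask.sum() == 2
        assert mask[1, 2, 3] and mask[2, 1, 0]

    def test_mask_superset_of_rasterized_shell(self, shell_cell, iso_grid):
        stack, _ = simulate_stack(
            [shell_cell], iso_grid, optics=OpticsSpec(psf_sigma=(0.1, 0.1, 0.1))
        )
        mask = threshold_percent_intensity(stack, 3.0)
        raster, _ = rasterize_cell(shell_cell, iso_grid)
        assert not np.any(raster & ~mask)

    def test_percent_out_of_range(self, grid_factory):
        grid = grid_factory(np.random.default_rng(0).random((4, 4, 4)))
        with pytest.raises(ValueError):
            threshold_percent_intensity(grid, -1.0)
        with pytest.raises(ValueError):
            threshold_percent_intensity(grid, 100.0)

    def test_percentile_mode(self, grid_factory):
        values = np.arange(1000, dtype=float).reshape(10, 10, 10)
        mask = threshold_percent_intensity(grid_factory(values), 30.0, mode="percentile")
        assert mask.sum() == 700


class TestDenoise:
    def test_isolated_voxel_removed(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        assert not denoise_objects(mask).any()

    def test_solid_ball_bulk_unchanged(self, ball_factory, iso_grid):
        from scipy import ndimage

        ball = ball_factory(2.0, iso_grid)
        out = denoise_objects(ball)
        eroded = ndimage.binary_erosion(ball)
        assert np.all(out[eroded])  # interior voxels survive
        assert not np.any(out & ~ndimage.binary_dilation(ball))

    def test_never_adds_outside_26_closure(self):
        from scipy import ndimage

        rng = np.random.default_rng(1)
        mask = rng.random((12, 12, 12)) < 0.3
        out = denoise_objects(mask)
        closure = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), bool))
        assert not np.any(out & ~closure)

    def test_salt_noise_volume_within_1pct(self, shell_fixture):
        mask, truth, _ = shell_fixture
        rng = np.random.default_rng(0)
        noisy = mask | (rng.random(mask.shape) < 0.001)
        out = denoise_objects(noisy)
        assert out.sum() == pytest.approx(mask.sum(), rel=0.01)

    def test_none_mode_is_identity(self):
        rng = np.random.default_rng(2)
        mask = rng.random((8, 8, 8)) < 0.2
        assert np.array_equal(denoise_objects(mask, mode="none"), mask)


class TestLabelAndFilter:
    def test_size_filter_semantics(self, iso_grid, ball_factory):
        # balls of ~10 and ~30 μm³ against the default 20 μm³ threshold
        grid = GridSpec(shape=(60, 60, 120), spacing=(0.1, 0.1, 0.1))
        small, _ = rasterize_cell(
            CellSpec(center=(3, 3, 2.5), outer_radius=1.336, wall_thickness=0.3, dead=True),
            grid,
        )
        big, _ = rasterize_cell(
            CellSpec(center=(3, 3, 8.0), outer_radius=1.927, wall_thickness=0.3, dead=True),
            grid,
        )
        objects = label_and_filter(small | big, spacing=grid.spacing, min_volume_um3=20.0)
        assert len(objects) == 1
        assert objects[0].volume_um3(grid.spacing) == pytest.approx(30.0, rel=0.05)

    def test_empty_mask(self):
        assert label_and_filter(np.zeros((5, 5, 5), bool), spacing=(0.1,) * 3) == []

    def test_border_touching_flagged(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[0:3, 2:5, 2:5] = True
        objects = label_and_filter(mask, spacing=(1.0,) * 3, min_volume_um3=0.0)
        assert len(objects) == 1 and objects[0].touches_border

    def test_connectivity_matters(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True  # diagonal neighbours
        assert len(label_and_filter(mask, (1.0,) * 3, connectivity=26, min_volume_um3=0)) == 1
        assert len(label_and_filter(mask, (1.0,) * 3, connectivity=6, min_volume_um3=0)) == 2


class TestClipToRoi:
    def test_no_rois_is_identity(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        objects = label_and_filter(mask, (1.0,) * 3, min_volume_um3=0)
        assert clip_to_roi(objects, None, mask.shape) == objects

    def test_two_touching_cells_split_by_rois(self):
        grid = GridSpec(shape=(40, 40, 76), spacing=(0.1, 0.1, 0.1))
        left = CellSpec(center=(2.0, 2.0, 1.9), outer_radius=1.5, wall_thickness=0.4)
        right = CellSpec(center=(2.0, 2.0, 5.0), outer_radius=1.5, wall_thickness=0.4)
        ml, _ = rasterize_cell(left, grid)
        mr, _ = rasterize_cell(right, grid)
        merged = ml | mr
        objects = label_and_filter(merged, grid.spacing, min_volume_um3=0.0)
        roi = np.zeros((40, 76), dtype=np.int32)
        roi[:, :35] = 1
        roi[:, 35:] = 2
        clipped = clip_to_roi(objects, roi, grid.shape)
        assert len(clipped) == 2
        assert sorted(o.roi_id for o in clipped) == [1, 2]
        for o in clipped:
            full = o.full_mask(grid.shape)
            outside = full & (np.broadcast_to(roi, grid.shape) != o.roi_id)
            assert not outside.any()

    def test_roi_covering_half_truncates(self):
        mask = np.zeros((6, 10, 10), bool)
        mask[2:4, 2:8, 2:8] = True
        objects = label_and_filter(mask, (1.0,) * 3, min_volume_um3=0)
        roi = np.zeros((10, 10), np.int32)
        roi[:, :5] = 1
        clipped = clip_to_roi(objects, roi, mask.shape)
        assert len(clipped) == 1
        assert clipped[0].voxel_count == 2 * 6 * 3


class TestCloseCell:
    def test_solid_ball_unchanged(self, ball_factory, iso_grid):
        ball = ball_factory(2.0, iso_grid)
        objects = label_and_filter(ball, iso_grid.spacing, min_volume_um3=0)
        cell = close_cell(objects[0], iso_grid.shape, iterations=10)
        assert int(cell.cell_mask.sum()) == pytest.approx(int(ball.sum()), rel=0.01)

    def test_shell_filled_to_outer_ball_within_3pct(self, shell_fixture, iso_grid):
        mask, truth, _ = shell_fixture
        objects = label_and_filter(mask, iso_grid.spacing, min_volume_um3=0)
        cell = close_cell(objects[0], iso_grid.shape, iterations=10)
        volume = cell.cell_mask.sum() * iso_grid.voxel_volume
        assert volume == pytest.approx(truth.outer_volume_um3, rel=0.03)

    def test_pinhole_sealed_and_lumen_filled(self, shell_fixture, iso_grid):
        mask, truth, _ = shell_fixture
        holed = mask.copy()
        zs = np.nonzero(mask)[0]
        holed[zs.max() - 5 :, 28:32, 28:32] = False  # punch a small aperture
        objects = label_and_filter(holed, iso_grid.spacing, min_volume_um3=0)
        cell = close_cell(objects[0], iso_grid.shape, iterations=10)
        volume = cell.cell_mask.sum() * iso_grid.voxel_volume
        assert volume == pytest.approx(truth.outer_volume_um3, rel=0.03)

    def test_result_contains_wall(self, shell_fixture, iso_grid):
        mask, _, _ = shell_fixture
        objects = label_and_filter(mask, iso_grid.spacing, min_volume_um3=0)
        cell = close_cell(objects[0], iso_grid.shape, iterations=10)
        assert not np.any(cell.wall_in_window & ~cell.cell_mask)


class TestFlagDead:
    def _segment_one(self, spec, grid, **kwargs):
        stack, _ = simulate_stack([spec], grid, **kwargs)
        return segment_cells(stack, NOISELESS)[0]

    def test_dead_cell_flagged(self, iso_grid):
        spec = CellSpec(
            center=(3, 3, 3), outer_radius=2.2, wall_thickness=0.5, intensity=100, dead=True
        )
        assert self._segment_one(spec, iso_grid).dead

    def test_live_cell_not_flagged(self, shell_cell, iso_grid):
        assert not self._segment_one(shell_cell, iso_grid).dead

    def test_dead_cell_flagged_under_blur_and_noise(self, aniso_grid):
        center = tuple(e / 2 for e in aniso_grid.extent_um)
        spec = CellSpec(
            center=center, outer_radius=3.1, wall_thickness=0.65, intensity=200, dead=True
        )
        stack, _ = simulate_stack(
            [spec],
            aniso_grid,
            optics=OpticsSpec(psf_sigma=(0.15, 0.1, 0.1), background=2.0),
            noise=NoiseSpec(poisson=True, seed=3),
        )
        assert segment_cells(stack)[0].dead

    def test_degenerate_no_interior_warns_false(self, iso_grid):
        # a small solid blob has no interior deeper than the margin
        mask = np.zeros(iso_grid.shape, bool)
        mask[28:32, 28:32, 28:32] = True
        grid = VoxelGrid(mask * 50.0, iso_grid.spacing)
        objects = label_and_filter(mask, iso_grid.spacing, min_volume_um3=0)
        cell = close_cell(objects[0], iso_grid.shape, iterations=2)
        with pytest.warns(UserWarning, match="interior"):
            assert flag_dead(cell, grid) is False


class TestSegmentCells:
    def test_all_zero_stack_empty(self, grid_factory):
        with pytest.warns(UserWarning, match="constant"):
            assert segment_cells(grid_factory(np.zeros((8, 8, 8)))) == []

    def test_sub_threshold_speckle_only_empty(self, grid_factory):
        values = np.zeros((20, 20, 20))
        values[10, 10, 10] = 100.0  # one bright voxel: ~0.001 μm³ << 20 μm³
        assert segment_cells(grid_factory(values)) == []

    def test_multi_cell_noiseless_recovery_within_10pct(self):
        grid = GridSpec(shape=(50, 260, 130), spacing=(0.2, 0.08, 0.08))
        cells = [
            CellSpec(
                center=(5.0, 3.4 + i * 7.0, 3.4 + j * 3.9),
                outer_radius=1.8,
                wall_thickness=0.45,
                intensity=150.0,
            )
            for i in range(3)
            for j in range(2)
        ]
        stack, truths = simulate_stack(cells, grid)
        meas = segment_cells(stack, NOISELESS)
        assert len(meas) == len(cells)
        mean_cell = np.mean([m.cell_volume_um3 for m in meas])
        mean_truth = np.mean([t.outer_volume_um3 for t in truths])
        assert mean_cell == pytest.approx(mean_truth, rel=0.10)
        mean_wall = np.mean([m.wall_volume_um3 for m in meas])
        assert mean_wall == pytest.approx(
            np.mean([t.wall_volume_um3 for t in truths]), rel=0.10
        )

    def test_measurement_invariants(self, shell_fixture, iso_grid):
        _, _, stack = shell_fixture
        for m in segment_cells(stack, NOISELESS):
            assert 0 < m.wall_volume_um3 <= m.cell_volume_um3
            assert 0 < m.ratio <= 1

    def test_oracle_equivalence_noiseless_unblurred(self, shell_fixture, iso_grid):
        mask, _, stack = shell_fixture
        meas, cells = segment_cells(stack, NOISELESS, return_objects=True)
        assert len(cells) == 1
        assert np.array_equal(cells[0].wall.full_mask(iso_grid.shape), mask)

    def test_translation_invariance(self, iso_grid):
        a = CellSpec(center=(2.5, 2.5, 2.5), outer_radius=1.6, wall_thickness=0.4, intensity=80)
        b = CellSpec(center=(3.1, 3.3, 3.5), outer_radius=1.6, wall_thickness=0.4, intensity=80)
        sa, _ = simulate_stack([a], iso_grid)
        sb, _ = simulate_stack([b], iso_grid)
        ma = segment_cells(sa, NOISELESS)[0]
        mb = segment_cells(sb, NOISELESS)[0]
        # whole-voxel shift (0.6/0.8/1.0 μm at 0.1 μm spacing): volumes identical
        assert ma.wall_volume_um3 == mb.wall_volume_um3
        assert ma.cell_volume_um3 == mb.cell_volume_um3

    def test_rotation_invariance_90deg(self, shell_fixture, iso_grid):
        _, _, stack = shell_fixture
        base = segment_cells(stack, NOISELESS)[0]
        for axes in ((0, 1), (1, 2), (0, 2)):
            rotated = VoxelGrid(np.rot90(stack.values, axes=axes).copy(), iso_grid.spacing)
            m = segment_cells(rotated, NOISELESS)[0]
            assert m.wall_volume_um3 == base.wall_volume_um3
            assert m.cell_volume_um3 == base.cell_volume_um3

    def test_threshold_monotonicity(self, shell_cell, iso_grid):
        stack, _ = simulate_stack(
            [shell_cell],
            iso_grid,
            optics=OpticsSpec(psf_sigma=(0.12, 0.1, 0.1), background=1.0),
            noise=NoiseSpec(poisson=True, seed=11),
        )
        volumes = []
        for pct in (1.0, 3.0, 8.0, 20.0):
            params = SegmentationParams(
                percent_intensity_lower=pct, noise_filter="none", min_object_volume_um3=5.0
            )
            meas = segment_cells(stack, params)
            volumes.append(sum(m.wall_volume_um3 for m in meas))
        assert all(a >= b for a, b in zip(volumes, volumes[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(percent_intensity_lower=100.0)
        with pytest.raises(ValueError):
            SegmentationParams(connectivity=4)
        with pytest.raises(ValueError):
            SegmentationParams(close_iterations=-1)

    def test_measurement_validation(self):
        with pytest.raises(ValueError):
            CellMeasurement(
                cell_id=1,
                wall_volume_um3=5.0,
                cell_volume_um3=4.0,
                ratio=1.25,
                dead=False,
                touches_border=False,
            )
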