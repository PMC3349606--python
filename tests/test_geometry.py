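"""Sector/ring coordinate system and extent models."""

import json

import numpy as np
import pytest

from segmentmar import (
    ExtentModel,
    GeometryError,
    N_SECTORS,
    Orientation,
    ShortAxisStack,
    compute_sector_grid,
    load_extent_model,
    remote_mask,
)
from segmentmar.geometry import (
    SECTOR_WIDTH,
    arc_to_row,
    pixel_angles,
    row_to_arc,
    sector_of_angle,
)

from conftest import make_annulus


def annulus_stack(n_slices=1, size=128):
    mask, centre = make_annulus(size)
    myo = np.broadcast_to(mask, (n_slices, size, size)).copy()
    image = np.zeros_like(myo, dtype=float)
    return ShortAxisStack(image=image, myo_mask=myo), centre


def paint_sectors(mask, centre, rv_angle):
    """Independent painting oracle: label each pixel with its sector index."""
    theta = pixel_angles(mask.shape, centre)
    rel = np.mod(theta - rv_angle, 2 * np.pi)
    labels = np.minimum((rel / SECTOR_WIDTH).astype(int), N_SECTORS - 1)
    return np.where(mask, labels, -1)


class TestSectorGrid:
    def test_anchor_pixel_maps_to_sector_0_and_half_turn_to_12(self):
        stack, (cr, cc) = annulus_stack()
        rv = 0.7
        grid = compute_sector_grid(stack, Orientation(rv_insertion_angle=rv))
        # pixel along the insertion direction from the centroid
        r_px = 18.0
        row = int(round(cr - np.sin(rv) * r_px))
        col = int(round(cc + np.cos(rv) * r_px))
        assert grid.sector_of_pixel[0, row, col] == 0
        row = int(round(cr - np.sin(rv + np.pi) * r_px))
        col = int(round(cc + np.cos(rv + np.pi) * r_px))
        assert grid.sector_of_pixel[0, row, col] == 12

    def test_reproduces_painted_sector_labels(self):
        stack, centre = annulus_stack()
        rv = 1.234
        painted = paint_sectors(stack.myo_mask[0], centre, rv)
        grid = compute_sector_grid(stack, Orientation(rv_insertion_angle=rv))
        myo = stack.myo_mask[0]
        agree = (grid.sector_of_pixel[0][myo] == painted[myo]).mean()
        assert agree >= 0.99

    def test_sectors_partition_the_myocardium(self, default_truth, default_grid):
        for s in range(default_truth.stack.n_slices):
            myo = default_truth.stack.myo_mask[s]
            labels = default_grid.sector_of_pixel[s]
            assert ((labels >= 0) == myo).all()
            counts = np.bincount(labels[myo], minlength=N_SECTORS)
            assert counts.sum() == myo.sum()

    def test_rotation_by_whole_sectors_shifts_labels_exactly(self):
        stack, _ = annulus_stack()
        rv = 0.3
        base = compute_sector_grid(stack, Orientation(rv_insertion_angle=rv))
        for k in (1, 5, 23):
            rotated = compute_sector_grid(
                stack, Orientation(rv_insertion_angle=rv + k * SECTOR_WIDTH))
            myo = stack.myo_mask[0]
            expected = (base.sector_of_pixel[0][myo] - k) % N_SECTORS
            assert (rotated.sector_of_pixel[0][myo] == expected).all()

    def test_rotation_equivariance_for_arbitrary_angle(self):
        stack, centre = annulus_stack()
        rv, delta = 0.3, 0.777
        rotated = compute_sector_grid(
            stack, Orientation(rv_insertion_angle=rv + delta))
        painted = paint_sectors(stack.myo_mask[0], centre, rv + delta)
        myo = stack.myo_mask[0]
        mismatch = (rotated.sector_of_pixel[0][myo] != painted[myo]).mean()
        assert mismatch < 0.02

    @pytest.mark.parametrize("n,expected", [
        (9, list(range(9))),
        (6, [0, 1, 3, 4, 6, 7]),
        (12, [0, 0, 1, 2, 3, 3, 4, 5, 6, 6, 7, 8]),
    ])
    def test_proportional_ring_assignment(self, n, expected):
        stack, _ = annulus_stack(n_slices=n)
        grid = compute_sector_grid(stack, Orientation(rv_insertion_angle=0.0))
        assert grid.ring_of_slice.tolist() == expected
        assert (np.diff(grid.ring_of_slice) >= 0).all()

    def test_degenerate_and_empty_slices(self):
        mask, _ = make_annulus(64, 8, 12)
        myo = np.zeros((3, 64, 64), dtype=bool)
        myo[0] = mask
        myo[1, 32, 32] = True          # single-pixel slice
        stack = ShortAxisStack(image=np.zeros_like(myo, float), myo_mask=myo)
        with pytest.warns(UserWarning, match="degenerate"):
            grid = compute_sector_grid(stack, Orientation(rv_insertion_angle=0.0))
        assert grid.empty_slices == {1, 2}

        empty = ShortAxisStack(image=np.zeros((2, 8, 8)),
                               myo_mask=np.zeros((2, 8, 8), bool))
        with pytest.raises(GeometryError, match="no slice"):
            compute_sector_grid(empty, Orientation(rv_insertion_angle=0.0))

    def test_sector_of_angle_bijection_with_angle_intervals(self):
        rv = 0.9
        k = np.arange(N_SECTORS)
        starts = rv + k * SECTOR_WIDTH + 1e-9
        ends = rv + (k + 1) * SECTOR_WIDTH - 1e-9
        assert (sector_of_angle(starts, rv) == k).all()
        assert (sector_of_angle(ends, rv) == k).all()


class TestExtentModels:
    def test_defaults_validate_for_all_arteries(self):
        for artery in ("LAD", "LCx", "RCA", "LM"):
            model = load_extent_model(artery)
            assert model.normal.shape == model.maximal.shape == (9, N_SECTORS)
            assert not np.any(model.normal & ~model.maximal)

    def test_lm_is_union_of_single_artery_models(self):
        parts = [load_extent_model(a) for a in ("LAD", "LCx", "RCA")]
        lm = load_extent_model("LM")
        assert (lm.normal == np.logical_or.reduce([p.normal for p in parts])).all()
        assert (lm.maximal == np.logical_or.reduce([p.maximal for p in parts])).all()

    def test_single_artery_rows_are_contiguous_arcs(self):
        for artery in ("LAD", "LCx", "RCA"):
            model = load_extent_model(artery)
            for row in model.maximal:
                assert row_to_arc(row) is not None

    def test_normal_outside_maximal_rejected(self, tmp_path):
        bad = {
            "artery": "LAD",
            "normal": np.ones((9, N_SECTORS), int).tolist(),
            "maximal": np.zeros((9, N_SECTORS), int).tolist(),
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(bad))
        with pytest.raises(GeometryError, match="subset"):
            load_extent_model("LAD", str(path))

    def test_wrong_shape_rejected(self, tmp_path):
        bad = {"artery": "LAD", "normal": [[0] * 10] * 9,
               "maximal": [[1] * 10] * 9}
        path = tmp_path / "shape.json"
        path.write_text(json.dumps(bad))
        with pytest.raises(GeometryError, match="must be 9x24"):
            load_extent_model("LAD", str(path))

    def test_arc_row_roundtrip_including_wraparound(self):
        for start, length in [(0, 0), (20, 10), (0, 24), (23, 2), (5, 1)]:
            assert row_to_arc(arc_to_row(start, length)) in (
                (start, length), (0, 0), (0, 24))


class TestRemoteMask:
    def _stack_grid(self):
        stack, _ = annulus_stack(n_slices=2)
        grid = compute_sector_grid(stack, Orientation(rv_insertion_angle=0.0))
        return stack, grid

    def test_full_maximal_gives_empty_remote(self):
        stack, grid = self._stack_grid()
        model = ExtentModel("LAD", np.zeros((9, N_SECTORS), bool),
                            np.ones((9, N_SECTORS), bool))
        assert remote_mask(stack, grid, model).sum() == 0

    def test_empty_maximal_gives_whole_myocardium(self):
        stack, grid = self._stack_grid()
        model = ExtentModel("LAD", np.zeros((9, N_SECTORS), bool),
                            np.zeros((9, N_SECTORS), bool))
        assert (remote_mask(stack, grid, model) == stack.myo_mask).all()

    def test_remote_complements_territory_on_phantom(self, default_truth,
                                                     default_grid, lad_model):
        rem = remote_mask(default_truth.stack, default_grid, lad_model)
        for s in range(default_truth.stack.n_slices):
            ring = default_grid.ring_of_slice[s]
            labels = default_grid.sector_of_pixel[s]
            myo = labels >= 0
            in_territory = myo & lad_model.maximal[ring][np.clip(labels, 0, None)]
            assert rem[s].sum() == myo.sum() - in_territory.sum()
            assert not np.any(rem[s] & in_territory)
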