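"""Globalization, fragment merging, grid ownership, uniformity statistics."""

import dataclasses

import numpy as np
import pytest

from seedgrid.detector.blob import blob_detect
from seedgrid.detector.losses import BBox, Detection
from seedgrid.errors import DataError
from seedgrid.preprocess import DetectionArea, binarize, segment_tiles
from seedgrid.synthetic import render
from seedgrid.uniformity import (
    GridOccupancy,
    assign_to_grid,
    empty_grid_rate,
    globalize,
    merge_cross_tile,
    miss_rate,
    occupancy,
    qualification_rate,
    report,
    test_error as rate_error,
)


def _run_detection(scene):
    binary = binarize(scene.image)
    raw = []
    for tile in scene.tiles:
        for det in blob_detect(tile.crop(binary)):
            raw.append(
                dataclasses.replace(det, source_tile=(tile.grid_row, tile.grid_col))
            )
    return merge_cross_tile(globalize(raw, scene.tiles))


class TestGlobalize:
    def test_tile_center_maps_to_rectangle_center(self):
        tiles = segment_tiles(DetectionArea(10, 50, 20, 100), 2, 2)
        det = Detection(bbox=BBox(0.5, 0.5, 0.2, 0.2), source_tile=(1, 1))
        (out,) = globalize([det], tiles)
        tile = [t for t in tiles if (t.grid_row, t.grid_col) == (1, 1)][0]
        assert out.bbox.cx == pytest.approx((tile.col_lo + tile.col_hi) / 2)
        assert out.bbox.cy == pytest.approx((tile.row_lo + tile.row_hi) / 2)

    def test_empty_input(self):
        tiles = segment_tiles(DetectionArea(0, 10, 0, 10), 1, 1)
        assert globalize([], tiles) == []

    def test_missing_tile_reference_rejected(self):
        tiles = segment_tiles(DetectionArea(0, 10, 0, 10), 1, 1)
        det = Detection(bbox=BBox(0.5, 0.5, 0.2, 0.2), source_tile=(3, 3))
        with pytest.raises(DataError):
            globalize([det], tiles)

    def test_simulator_centers_match_manifest(self, small_scene):
        dets = _run_detection(small_scene)
        got = sorted((d.bbox.cy, d.bbox.cx) for d in dets)
        want = sorted(
            (
                (rec.bbox_px[0] + rec.bbox_px[2]) / 2,
                (rec.bbox_px[1] + rec.bbox_px[3]) / 2,
            )
            for rec in small_scene.manifest
        )
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1.0)


class TestMergeCrossTile:
    def test_split_seed_reunites(self):
        left = Detection(
            bbox=BBox.from_corners(90, 40, 100, 48, frame="tray_px"),
            source_tile=(0, 0),
        )
        right = Detection(
            bbox=BBox.from_corners(100, 41, 108, 49, frame="tray_px"),
            source_tile=(0, 1),
        )
        (merged,) = merge_cross_tile([left, right])
        assert merged.bbox.x_lo == 90 and merged.bbox.x_hi == 108
        assert merged.source_tile is None

    def test_non_adjacent_tiles_untouched(self):
        a = Detection(bbox=BBox(50, 50, 8, 8, frame="tray_px"), source_tile=(0, 0))
        b = Detection(bbox=BBox(52, 50, 8, 8, frame="tray_px"), source_tile=(0, 5))
        assert len(merge_cross_tile([a, b], iou_threshold=0.9)) == 2

    def test_straddling_scenes_recover_manifest_count(self, small_plan):
        """50 trays with 15% boundary-straddling seeds: counts match truth."""
        matches = 0
        for s in range(50):
            scene = render(
                plan=small_plan,
                n_seeds=150,
                method="broadcast",
                seed=400 + s,
                straddle_frac=0.15,
            )
            dets = _run_detection(scene)
            matches += int(len(dets) == scene.n_seeds)
        assert matches >= 0.99 * 50


@pytest.fixture(scope="module")
def tiles():
    # 4 x 4 grid of exact 50 x 50 px tiles
    return segment_tiles(DetectionArea(0, 200, 0, 200), 4, 4)


class TestAssignToGrid:
    def test_fully_inside(self, tiles):
        det = Detection(bbox=BBox(175, 125, 10, 10, frame="tray_px"))
        assert assign_to_grid(det, tiles) == (2, 3)

    def test_majority_area_wins(self, tiles):
        # 70 % of the box in the left grid of a straddled vertical cut
        det = Detection(bbox=BBox.from_corners(43, 20, 53, 30, frame="tray_px"))
        assert assign_to_grid(det, tiles) == (0, 0)
        det = Detection(bbox=BBox.from_corners(47, 20, 57, 30, frame="tray_px"))
        assert assign_to_grid(det, tiles) == (0, 1)

    def test_four_way_tie_takes_top_left(self, tiles):
        det = Detection(bbox=BBox(50.0, 50.0, 10, 10, frame="tray_px"))
        # exhaustive four-way area computation: all quarters are 25 px^2
        assert assign_to_grid(det, tiles) == (0, 0)

    def test_outside_area_rejected(self, tiles):
        det = Detection(bbox=BBox(500, 500, 10, 10, frame="tray_px"))
        with pytest.raises(DataError):
            assign_to_grid(det, tiles)


class TestOccupancy:
    def test_empty_detections(self):
        tiles = segment_tiles(DetectionArea(0, 100, 0, 100), 2, 2)
        occ = occupancy([], tiles)
        assert occ.counts.shape == (2, 2) and occ.counts.sum() == 0

    def test_one_per_grid_center(self):
        tiles = segment_tiles(DetectionArea(0, 100, 0, 100), 2, 2)
        dets = [
            Detection(
                bbox=BBox(
                    (t.col_lo + t.col_hi) / 2,
                    (t.row_lo + t.row_hi) / 2,
                    6,
                    6,
                    frame="tray_px",
                )
            )
            for t in tiles
        ]
        assert (occupancy(dets, tiles).counts == 1).all()

    def test_simulator_counts_exact(self, small_scene):
        dets = _run_detection(small_scene)
        occ = occupancy(dets, small_scene.tiles, small_scene.plan)
        assert np.array_equal(occ.counts, small_scene.truth_occupancy().counts)

    def test_permutation_invariance(self, small_scene, rng):
        dets = _run_detection(small_scene)
        shuffled = list(dets)
        rng.shuffle(shuffled)
        a = report(occupancy(dets, small_scene.tiles))
        b = report(occupancy(shuffled, small_scene.tiles))
        assert a == b


class TestRates:
    def test_all_pairs_qualify(self):
        occ = GridOccupancy(counts=np.full((3, 4), 2))
        assert qualification_rate(occ) == 100.00
        assert empty_grid_rate(occ) == 0.00

    def test_half_qualify(self):
        occ = GridOccupancy(counts=np.array([[0, 2], [4, 2]]))
        assert qualification_rate(occ) == 50.00
        assert empty_grid_rate(occ) == 25.00

    def test_matches_brute_force_on_random_counts(self, rng):
        counts = rng.integers(0, 6, size=(18, 41))
        occ = GridOccupancy(counts=counts)
        brute_q = sum(
            1 for r in range(18) for c in range(41) if 1 <= counts[r, c] <= 3
        )
        brute_e = sum(1 for r in range(18) for c in range(41) if counts[r, c] == 0)
        assert qualification_rate(occ) == round(brute_q / 738 * 100, 2)
        assert empty_grid_rate(occ) == round(brute_e / 738 * 100, 2)
        # complement: qualified + empty + overfilled = all grids
        over = 738 - brute_q - brute_e
        assert brute_q + brute_e + over == 738

    def test_zero_grids_rejected(self):
        occ = GridOccupancy(counts=np.zeros((0, 0), dtype=int))
        with pytest.raises(DataError):
            qualification_rate(occ)


class TestScalarMetrics:
    def test_miss_rate_worked_example(self):
        assert miss_rate(13, 8) == 38.46

    def test_miss_rate_extremes(self):
        assert miss_rate(7, 7) == 0.00
        assert miss_rate(10, 0) == 100.00

    def test_miss_rate_domain(self):
        with pytest.raises(DataError):
            miss_rate(0, 0)
        with pytest.raises(DataError):
            miss_rate(5, 6)

    def test_test_error_table_rows(self):
        assert rate_error(70.88, 68.75) == 2.13
        assert rate_error(80.82, 82.77) == -1.95
        assert rate_error(50.0, 50.0) == 0.00

    def test_test_error_domain(self):
        with pytest.raises(DataError):
            rate_error(101.0, 50.0)
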