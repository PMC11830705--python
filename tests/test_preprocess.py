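"""Binarization, border localization, rectification, and tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st


from seedgrid.errors import BordersNotFoundError, DataError, TrayFrameNotFoundError
from seedgrid.preprocess import (
    DetectionArea,
    ProjectionProfile,
    affine_correct,
    binarize,
    extract_tray_quadrilateral,
    locate_borders,
    locate_detection_area,
    projection_profiles,
    segment_tiles,
)
from seedgrid.synthetic import apply_perspective, render


class TestBinarize:
    def test_constant_dark_image_is_all_background(self):
        assert binarize(np.full((10, 10), 5)).sum() == 0

    def test_two_level_image_separates_exactly(self):
        img = np.full((20, 20), 10)
        img[5:10, 5:10] = 200
        out = binarize(img)
        assert np.array_equal(out == 1, img == 200)

    def test_noiseless_render_recovers_drawn_foreground(self, small_scene):
        # soil is 60, seeds/border 200/230: any threshold between separates
        expected = small_scene.image > 130
        assert np.array_equal(binarize(small_scene.image).astype(bool), expected)

    def test_empty_image_rejected(self):
        with pytest.raises(DataError):
            binarize(np.empty((0, 0)))


class TestProjectionProfiles:
    def test_single_pixel(self):
        img = np.zeros((7, 9), dtype=np.uint8)
        img[3, 5] = 1
        prof = projection_profiles(img)
        assert prof.row_sums[3] == 1 and prof.row_sums.sum() == 1
        assert prof.col_sums[5] == 1 and prof.col_sums.sum() == 1

    def test_matches_brute_force_double_loop(self, rng):
        img = (rng.uniform(size=(20, 30)) < 0.4).astype(np.uint8)
        prof = projection_profiles(img)
        rows = [sum(img[i, j] for j in range(30)) for i in range(20)]
        cols = [sum(img[i, j] for i in range(20)) for j in range(30)]
        assert list(prof.row_sums) == rows
        assert list(prof.col_sums) == cols

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mass_conservation(self, seed):
        img = (np.random.default_rng(seed).uniform(size=(13, 17)) < 0.3).astype(np.uint8)
        prof = projection_profiles(img)
        assert prof.row_sums.sum() == prof.col_sums.sum() == img.sum()


class TestLocateBorders:
    def test_step_profile_inner_edges(self):
        """Border bands at [100,120) and [880,900); interior speckle at 30."""
        col = np.zeros(1000)
        col[100:120] = 500
        col[120:880] = 30
        col[880:900] = 500
        prof = ProjectionProfile(row_sums=col.copy(), col_sums=col)
        borders = locate_borders(prof)
        assert (borders.b1, borders.c1) == (120, 880)
        assert (borders.b2, borders.c2) == (120, 880)

    def test_all_zero_profile_fails(self):
        prof = ProjectionProfile(row_sums=np.zeros(50), col_sums=np.zeros(50))
        with pytest.raises(BordersNotFoundError):
            locate_borders(prof)

    def test_all_foreground_image_fails(self):
        with pytest.raises(BordersNotFoundError):
            locate_detection_area(np.ones((50, 80), dtype=np.uint8))

    def test_recovers_rendered_inner_cavity_exactly(self, small_scene):
        area = locate_detection_area(binarize(small_scene.image))
        truth = small_scene.area
        assert abs(area.row_lo - truth.row_lo) <= 2
        assert abs(area.row_hi - truth.row_hi) <= 2
        assert abs(area.col_lo - truth.col_lo) <= 2
        assert abs(area.col_hi - truth.col_hi) <= 2


def _border_ring(shape, lo_r, hi_r, lo_c, hi_c, band):
    img = np.zeros(shape, dtype=np.uint8)
    img[lo_r:hi_r, lo_c:hi_c] = 1
    img[lo_r + band : hi_r - band, lo_c + band : hi_c - band] = 0
    return img


class TestTrayQuadrilateral:
    def test_axis_aligned_rectangle_corners(self):
        img = _border_ring((200, 300), 10, 190, 15, 285, 12)
        quad = extract_tray_quadrilateral(img, min_area_frac=0.5)
        expected = np.array([[10, 15], [10, 284], [189, 284], [189, 15]])
        assert np.abs(quad - expected).max() <= 2

    def test_rotated_rectangle_corners(self):
        """Ring drawn from analytically rotated corners: corners recovered."""
        from skimage.draw import polygon as draw_polygon

        theta = np.deg2rad(10)
        center = np.array([200.0, 200.0])
        rot_mat = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )

        def rotated(corners):
            return (np.asarray(corners, dtype=float) - center) @ rot_mat.T + center

        outer = rotated([[100, 60], [100, 340], [300, 340], [300, 60]])
        inner = rotated([[114, 74], [114, 326], [286, 326], [286, 74]])
        img = np.zeros((400, 400), dtype=np.uint8)
        rr, cc = draw_polygon(outer[:, 0], outer[:, 1], shape=img.shape)
        img[rr, cc] = 1
        rr, cc = draw_polygon(inner[:, 0], inner[:, 1], shape=img.shape)
        img[rr, cc] = 0
        quad = extract_tray_quadrilateral(img, min_area_frac=0.1)
        assert np.abs(quad - outer).max() <= 2

    def test_blank_image_raises(self):
        with pytest.raises(TrayFrameNotFoundError):
            extract_tray_quadrilateral(np.zeros((50, 50), dtype=np.uint8))


class TestAffineCorrect:
    def test_identity_quad_preserves_image(self, rng):
        img = rng.uniform(0, 255, size=(40, 60))
        quad = np.array([[0, 0], [0, 59], [39, 59], [39, 0]], dtype=float)
        out = affine_correct(img, quad, (40, 60))
        assert np.abs(out - img).mean() < 1e-6

    def test_degenerate_quad_raises(self):
        quad = np.array([[0, 0], [0, 10], [0, 20], [10, 0]], dtype=float)
        with pytest.raises(DataError):
            affine_correct(np.zeros((20, 20)), quad, (20, 20))

    def test_perspective_roundtrip_recovers_tray(self, small_scene):
        warped, quad_true = apply_perspective(small_scene.image, margin_px=20, seed=9)
        quad = extract_tray_quadrilateral(binarize(warped), min_area_frac=0.3)
        assert np.abs(quad - quad_true).max() <= 2
        h, w = small_scene.image.shape
        rect = affine_correct(warped, quad, (h - 40, w - 40))
        orig = small_scene.image[20 : h - 20, 20 : w - 20].astype(float)
        assert np.abs(rect - orig).mean() < 4.0


class TestSegmentTiles:
    def test_planned_tile_count(self):
        area = DetectionArea(0, 820, 0, 580)
        tiles = segment_tiles(area, 18, 41)
        assert len(tiles) == 738
        assert tiles[0].grid_row == 0 and tiles[0].grid_col == 0
        assert tiles[-1].grid_row == 17 and tiles[-1].grid_col == 40

    def test_single_tile_equals_area(self):
        area = DetectionArea(5, 25, 10, 40)
        (tile,) = segment_tiles(area, 1, 1)
        assert (tile.row_lo, tile.row_hi, tile.col_lo, tile.col_hi) == (5, 25, 10, 40)

    def test_partition_exhaustive(self):
        """Disjoint cover with <=1 px size spread, all (rows, cols) <= 10."""
        area = DetectionArea(3, 40, 7, 60)  # 37 x 53 px
        for rows in range(1, 11):
            for cols in range(1, 11):
                tiles = segment_tiles(area, rows, cols)
                cover = np.zeros((37, 53), dtype=int)
                heights, widths = set(), set()
                for t in tiles:
                    cover[t.row_lo - 3 : t.row_hi - 3, t.col_lo - 7 : t.col_hi - 7] += 1
                    heights.add(t.height)
                    widths.add(t.width)
                assert (cover == 1).all()
                assert max(heights) - min(heights) <= 1
                assert max(widths) - min(widths) <= 1

    def test_too_many_tiles_rejected(self):
        from seedgrid.errors import ConfigError

        with pytest.raises(ConfigError):
            segment_tiles(DetectionArea(0, 5, 0, 5), 10, 2)
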