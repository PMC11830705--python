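"""Raw tray photograph -> ordered unit seed-grid tiles.

Stages: binarization, tray-frame corner extraction, perspective correction,
projection-profile localization of the detection area (the soil cavity inside
the bright tray border), and sliding-window tiling into the grid planned by
:mod:`seedgrid.grid_plan`.

Conventions used throughout: 0-based, half-open ``[lo, hi)`` pixel
rectangles in ``(row, col)`` order; binary foreground is 1 = bright content
(seed or tray border), background 0.  Tiles are emitted row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import ProjectiveTransform, warp

from .errors import BordersNotFoundError, ConfigError, DataError, TrayFrameNotFoundError


@dataclass(frozen=True)
class ProjectionProfile:
    """Cumulative foreground counts per row and per column.

    ``row_sums[i]`` counts foreground pixels in image row ``i``;
    ``col_sums[j]`` in column ``j``.  Both sum to the total foreground mass.
    """

    row_sums: np.ndarray
    col_sums: np.ndarray


@dataclass(frozen=True)
class BorderLocations:
    """Inner edges of the four tray-border bands, as pixel indices.

    ``b1``/``c1`` are column indices (left/right border inner edges),
    ``b2``/``c2`` row indices (top/bottom).  The detection area is the
    half-open rectangle ``[b2, c2) x [b1, c1)``.
    """

    b1: int
    c1: int
    b2: int
    c2: int


@dataclass(frozen=True)
class DetectionArea:
    """Half-open pixel rectangle of the tray's soil cavity."""

    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int

    @property
    def height(self) -> int:
        return self.row_hi - self.row_lo

    @property
    def width(self) -> int:
        return self.col_hi - self.col_lo

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_lo : self.row_hi, self.col_lo : self.col_hi]


@dataclass(frozen=True)
class SeedGridTile:
    """One unit seed-grid rectangle within the detection area."""

    grid_row: int
    grid_col: int
    row_lo: int
    row_hi: int
    col_lo: int
    col_hi: int

    @property
    def height(self) -> int:
        return self.row_hi - self.row_lo

    @property
    def width(self) -> int:
        return self.col_hi - self.col_lo

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_lo : self.row_hi, self.col_lo : self.col_hi]


def binarize(image: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale image to a {0, 1} foreground mask.

    Foreground (1) is the bright class: seeds and the tray border both image
    brighter than nursery soil.  ``method="otsu"`` picks the threshold from
    the histogram; ``method="fixed"`` uses the supplied ``threshold``.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        image = image.mean(axis=2)
    if image.ndim != 2 or image.size == 0:
        raise DataError("binarize expects a non-empty 2-D (or RGB) image")
    if method == "otsu":
        if image.min() == image.max():
            return np.zeros(image.shape, dtype=np.uint8)
        t = threshold_otsu(image)
    elif method == "fixed":
        if threshold is None:
            raise ConfigError("fixed-threshold binarization needs a threshold")
        t = threshold
    else:
        raise ConfigError(f"unknown binarization method {method!r}")
    return (image > t).astype(np.uint8)


def _order_corners_clockwise(pts: np.ndarray) -> np.ndarray:
    """Order 4 (row, col) points clockwise starting at top-left."""
    c = pts.mean(axis=0)
    # clockwise in (row, col) screen coordinates
    ang = np.arctan2(pts[:, 0] - c[0], pts[:, 1] - c[1])
    pts = pts[np.argsort(ang)]
    start = int(np.argmin(pts.sum(axis=1)))
    return np.roll(pts, -start, axis=0)


def extract_tray_quadrilateral(binary: np.ndarray, min_area_frac: float = 0.5) -> np.ndarray:
    """Corners of the dominant (possibly perspective-distorted) tray outline.

    Finds the largest 8-connected foreground component and picks the four
    convex-hull points extremal along the diagonal directions (min r+c,
    max c-r, max r+c, max r-c), i.e. the quadrilateral corners of a tray
    photographed upright or tilted by less than 45 degrees.  Returns them
    clockwise from top-left as float ``(row, col)`` pairs.  The corner
    quadrilateral must cover at least ``min_area_frac`` of the image, else
    the tray frame is declared missing.
    """
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise DataError("expected a 2-D binary image")
    lab = label(binary > 0, connectivity=2)
    if lab.max() == 0:
        raise TrayFrameNotFoundError("tray frame not found: no foreground")
    props = max(regionprops(lab), key=lambda p: p.area)
    coords = props.coords.astype(float)
    hull_pts = coords[ConvexHull(coords).vertices]
    r, c = hull_pts[:, 0], hull_pts[:, 1]
    corners = np.array(
        [
            hull_pts[np.argmin(r + c)],  # top-left
            hull_pts[np.argmax(c - r)],  # top-right
            hull_pts[np.argmax(r + c)],  # bottom-right
            hull_pts[np.argmax(r - c)],  # bottom-left
        ]
    )
    quad_area = Polygon([tuple(p) for p in corners]).area
    if quad_area < min_area_frac * binary.size:
        raise TrayFrameNotFoundError(
            f"tray frame not found: dominant contour covers "
            f"{quad_area / binary.size:.2%} < {min_area_frac:.0%} of the image"
        )
    return _order_corners_clockwise(corners)


def affine_correct(
    image: np.ndarray,
    quad: np.ndarray,
    out_shape: tuple[int, int],
) -> np.ndarray:
    """Warp the quadrilateral tray outline to an upright rectangle.

    ``quad`` holds 4 ``(row, col)`` corners clockwise from top-left;
    ``out_shape`` is the target ``(height, width)``.  A 4-point homography is
    used (a pure affine map cannot fit 4 arbitrary corners of a perspective
    photograph); the corners map exactly onto the output rectangle corners.
    """
    quad = np.asarray(quad, dtype=float)
    if quad.shape != (4, 2):
        raise ConfigError("quad must be 4 (row, col) points")
    h, w = out_shape
    if h < 1 or w < 1:
        raise ConfigError("output shape must be positive")
    # degenerate if any three corners are collinear
    for i in range(4):
        a, b, c = quad[i], quad[(i + 1) % 4], quad[(i + 2) % 4]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) < 1e-9:
            raise DataError("degenerate quadrilateral: collinear corners")
    dst_rc = np.array([[0, 0], [0, w - 1], [h - 1, w - 1], [h - 1, 0]], dtype=float)
    # skimage transforms work in (x, y) = (col, row)
    src_xy = quad[:, ::-1]
    dst_xy = dst_rc[:, ::-1]
    tform = ProjectiveTransform.from_estimate(src_xy, dst_xy)
    if not tform:
        raise DataError("homography estimation failed")
    warped = warp(
        np.asarray(image, dtype=float),
        tform.inverse,
        output_shape=(h, w),
        order=1,
        preserve_range=True,
    )
    return warped


def projection_profiles(binary: np.ndarray) -> ProjectionProfile:
    """Row and column cumulative foreground sums of a binary image."""
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise DataError("expected a 2-D binary image")
    b = (binary > 0).astype(np.int64)
    return ProjectionProfile(row_sums=b.sum(axis=1), col_sums=b.sum(axis=0))


def _band_inner_edges(
    profile: np.ndarray,
    threshold_frac: float,
    drop_frac: float,
    min_run: int,
) -> tuple[int, int]:
    """Inner edges of the two high bands at either end of a 1-D profile.

    Scanning inward from each end: the band starts at the first value
    >= ``threshold_frac * max`` and ends where the profile falls back below
    ``drop_frac`` of the running band maximum.  Returns the half-open
    ``(lo, hi)`` interior interval between the two bands.
    """
    profile = np.asarray(profile, dtype=float)
    n = profile.size
    peak = profile.max() if n else 0.0
    if peak <= 0:
        raise BordersNotFoundError("borders not found: empty profile")
    t = threshold_frac * peak

    def scan(idx_iter):
        start = None
        band_max = 0.0
        length = 0
        for i in idx_iter:
            v = profile[i]
            if start is None:
                if v >= t:
                    start = i
                    band_max = v
                    length = 1
            else:
                if v < drop_frac * band_max:
                    if length < min_run:
                        raise BordersNotFoundError(
                            f"borders not found: border run shorter than {min_run} px"
                        )
                    return i
                band_max = max(band_max, v)
                length += 1
        raise BordersNotFoundError("borders not found: band never falls back")

    lo = scan(range(n))
    hi_rev = scan(range(n - 1, -1, -1))
    hi = hi_rev + 1  # half-open upper edge
    if not lo < hi:
        raise BordersNotFoundError("borders not found: border runs never separate")
    return lo, hi


def locate_borders(
    profile: ProjectionProfile,
    threshold_frac: float = 0.05,
    drop_frac: float = 0.5,
    min_run: int = 5,
) -> BorderLocations:
    """Locate the inner edges of the four tray-border bands.

    The projection of a corrected tray image shows an abrupt high band at
    each end (the bright border) with a low interior between them.  The
    inner edge is where the profile falls back from its initial rise: the
    first index past the band where the value drops below ``drop_frac`` of
    the band's running maximum.  ``threshold_frac`` (of the profile maximum)
    detects the band's outer onset; ``min_run`` rejects spurious spikes
    narrower than a plausible border band.
    """
    b1, c1 = _band_inner_edges(profile.col_sums, threshold_frac, drop_frac, min_run)
    b2, c2 = _band_inner_edges(profile.row_sums, threshold_frac, drop_frac, min_run)
    return BorderLocations(b1=b1, c1=c1, b2=b2, c2=c2)


def locate_detection_area(binary: np.ndarray, **kwargs) -> DetectionArea:
    """Detection area (soil cavity) of a corrected binary tray image.

    Keyword arguments are forwarded to :func:`locate_borders`.
    """
    borders = locate_borders(projection_profiles(binary), **kwargs)
    area = DetectionArea(
        row_lo=borders.b2, row_hi=borders.c2, col_lo=borders.b1, col_hi=borders.c1
    )
    if area.height <= 0 or area.width <= 0:
        raise BordersNotFoundError("borders not found: empty detection area")
    return area


def tile_cut_positions(lo: int, hi: int, n: int) -> np.ndarray:
    """``n + 1`` integer cut positions evenly spanning ``[lo, hi)``.

    Cumulative rounding of the exact even spacing, so consecutive tile sizes
    differ by at most 1 px and the cuts always start at ``lo`` and end at
    ``hi``.
    """
    return np.round(np.linspace(lo, hi, n + 1)).astype(int)


def segment_tiles(area: DetectionArea, rows: int, cols: int) -> list[SeedGridTile]:
    """Partition the detection area into ``rows x cols`` seed-grid tiles.

    Tiles are returned row-major, are pairwise disjoint, and exactly cover
    the area; per-axis sizes differ by at most 1 px.
    """
    if rows < 1 or cols < 1:
        raise ConfigError("rows and cols must be >= 1")
    if rows > area.height or cols > area.width:
        raise ConfigError(
            f"cannot cut a {area.height}x{area.width} px area into "
            f"{rows}x{cols} tiles"
        )
    rcuts = tile_cut_positions(area.row_lo, area.row_hi, rows)
    ccuts = tile_cut_positions(area.col_lo, area.col_hi, cols)
    return [
        SeedGridTile(
            grid_row=r,
            grid_col=c,
            row_lo=int(rcuts[r]),
            row_hi=int(rcuts[r + 1]),
            col_lo=int(ccuts[c]),
            col_hi=int(ccuts[c + 1]),
        )
        for r in range(rows)
        for c in range(cols)
    ]
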