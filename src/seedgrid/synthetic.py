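"""Synthetic tray scenes with exact ground truth.

No public seed-tray photograph collection is available, so every pipeline
stage is validated on rendered scenes: a dark margin, a bright tray-border
band, a soil-gray detection area (optionally with Gaussian texture noise),
and bright elliptical seeds with random orientation.  The manifest records
every seed's center, axes, pixel bounding box and true grid membership, the
latter computed with the same largest-coverage rule the pipeline uses, so
manifest-versus-pipeline agreement is a meaningful end-to-end oracle.

Placement emulates the three sowing methods: *broadcast* scatters seeds
uniformly; the *strip* modes confine seeds laterally to 18 bands (one per
seeder row) and meter them more regularly along the tray length, the
ditching variant using narrower bands and steadier metering than the
no-ditching variant — which is what makes its rendered trays measurably
more uniform, mirroring field behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .detector.losses import BBox, Detection
from .errors import ConfigError
from .grid_plan import (
    GridPlan,
    SowingSpec,
    TrayGeometry,
    build_grid_plan,
    expected_seed_count,
)
from .preprocess import DetectionArea, SeedGridTile, segment_tiles, tile_cut_positions
from .uniformity import assign_to_grid, occupancy, report

#: default rendering scale; one seed-grid frame spans roughly 40 px
DEFAULT_SCALE_PX_PER_MM = 2.8

#: gray levels chosen so Otsu separation is unambiguous
SOIL_LEVEL = 60
SEED_LEVEL = 200
BORDER_LEVEL = 230

#: lateral band width as a fraction of the strip pitch
DEFAULT_JITTER = {"strip_no_ditch": 0.7, "strip_ditch": 0.4}

#: along-length spacing jitter (fraction of the mean spacing)
LENGTH_JITTER = {"broadcast": None, "strip_no_ditch": 1.4, "strip_ditch": 0.7}


@dataclass(frozen=True)
class SeedRecord:
    """Ground truth for one rendered seed."""

    center_rc: tuple[float, float]
    axes_px: tuple[float, float]  # (major, minor), full lengths
    angle_rad: float
    bbox_px: tuple[int, int, int, int]  # half-open (row_lo, col_lo, row_hi, col_hi)
    grid: tuple[int, int]


@dataclass
class TrayScene:
    """A rendered tray image plus everything needed to check the pipeline."""

    image: np.ndarray
    manifest: list[SeedRecord]
    plan: GridPlan
    area: DetectionArea
    tiles: list[SeedGridTile] = field(repr=False, default_factory=list)
    method: str = "broadcast"
    density_g: float | None = None
    seed: int = 0

    @property
    def n_seeds(self) -> int:
        return len(self.manifest)

    def truth_occupancy(self):
        counts = np.zeros((self.plan.rows, self.plan.cols), dtype=int)
        for rec in self.manifest:
            counts[rec.grid] += 1
        from .uniformity import GridOccupancy

        return GridOccupancy(counts=counts, plan=self.plan)

    def truth_detections(self) -> list[Detection]:
        dets = []
        for rec in self.manifest:
            r0, c0, r1, c1 = rec.bbox_px
            dets.append(
                Detection(bbox=BBox.from_corners(c0, r0, c1, r1, frame="tray_px"))
            )
        return dets


def _seed_half_extents(axes_px, angle):
    """Half width/height of the bounding box of a rotated ellipse."""
    a, b = axes_px[0] / 2.0, axes_px[1] / 2.0
    # skimage draw.ellipse puts the first (major) radius along rows at rotation 0
    half_r = math.hypot(a * math.cos(angle), b * math.sin(angle))
    half_c = math.hypot(a * math.sin(angle), b * math.cos(angle))
    return half_r, half_c


def sample_positions(
    plan: GridPlan,
    n_seeds: int,
    method: str = "broadcast",
    jitter: float | None = None,
    seed: int = 0,
    *,
    scale_px_per_mm: float = DEFAULT_SCALE_PX_PER_MM,
    seed_axes_px: tuple[float, float] = (8.0, 3.0),
    min_gap_px: float = 2.0,
    straddle_frac: float = 0.0,
    max_tries: int = 500,
):
    """Sample seed centers and orientations in detection-area pixel frame.

    Returns ``(centers, angles)`` with centers as ``(row, col)`` floats.
    Broadcast sampling is uniform over the area; strip modes confine the
    lateral (row) coordinate to 18 bands of width ``jitter`` x pitch and
    meter seeds along the length with method-specific regularity.  A
    placement is rejected unless the seed's bounding box keeps at least
    ``min_gap_px`` clear of every other seed's box (so seeds never touch)
    and, unless the seed is one of the ``straddle_frac`` fraction allowed
    to straddle, stays strictly inside its tile.
    """
    if n_seeds < 0:
        raise ConfigError("n_seeds must be >= 0")
    if jitter is None:
        jitter = DEFAULT_JITTER.get(method, 1.0)
    if not 0.0 < jitter <= 1.0:
        raise ConfigError("jitter must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    area_h = int(round(plan.tray.inner_width_mm * scale_px_per_mm))
    area_w = int(round(plan.tray.inner_length_mm * scale_px_per_mm))
    rcuts = tile_cut_positions(0, area_h, plan.rows)
    ccuts = tile_cut_positions(0, area_w, plan.cols)
    pitch = area_h / plan.rows

    straddlers = set()
    if straddle_frac > 0 and n_seeds > 0:
        k = int(round(straddle_frac * n_seeds))
        straddlers = set(rng.choice(n_seeds, size=k, replace=False).tolist())

    # per-strip allocation and along-length metering for strip modes
    if method in ("strip_no_ditch", "strip_ditch"):
        base, extra = divmod(n_seeds, plan.rows)
        per_strip = [base + (1 if i < extra else 0) for i in range(plan.rows)]
        lj = LENGTH_JITTER[method]
        proposals = []
        for strip, m in enumerate(per_strip):
            if m == 0:
                continue
            r_center = (strip + 0.5) * pitch
            half_band = 0.5 * jitter * pitch
            spacing = area_w / m
            cols_pos = (np.arange(m) + 0.5) * spacing + rng.uniform(
                -0.5 * lj * spacing, 0.5 * lj * spacing, size=m
            )
            rows_pos = r_center + rng.uniform(-half_band, half_band, size=m)
            for rp, cp in zip(rows_pos, cols_pos):
                proposals.append((rp, cp, r_center, half_band, spacing))
        rng.shuffle(proposals)
    elif method == "broadcast":
        proposals = None
    else:
        raise ConfigError(f"unknown sowing method {method!r}")

    cell = seed_axes_px[0] + min_gap_px
    grid_index: dict[tuple[int, int], list[tuple[float, float, float, float]]] = {}

    def ok_separation(p, half_r, half_c):
        gi, gj = int(p[0] // cell), int(p[1] // cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for qr, qc, qhr, qhc in grid_index.get((gi + di, gj + dj), ()):
                    if (
                        abs(p[0] - qr) < half_r + qhr + min_gap_px
                        and abs(p[1] - qc) < half_c + qhc + min_gap_px
                    ):
                        return False
        return True

    def ok_placement(i, p, half_r, half_c):
        # always stay inside the detection area with margin
        if not (half_r + 2 <= p[0] <= area_h - half_r - 2):
            return False
        if not (half_c + 2 <= p[1] <= area_w - half_c - 2):
            return False
        if i in straddlers:
            return True
        r_idx = int(np.searchsorted(rcuts, p[0], side="right")) - 1
        c_idx = int(np.searchsorted(ccuts, p[1], side="right")) - 1
        return (
            p[0] - half_r >= rcuts[r_idx] + 3
            and p[0] + half_r <= rcuts[r_idx + 1] - 3
            and p[1] - half_c >= ccuts[c_idx] + 3
            and p[1] + half_c <= ccuts[c_idx + 1] - 3
        )

    centers, angles = [], []
    for i in range(n_seeds):
        placed = False
        for attempt in range(max_tries):
            angle = rng.uniform(0, math.pi)
            if proposals is not None and i < len(proposals):
                rp, cp, r_center, half_band, spacing = proposals[i]
                if attempt == 0:
                    p = np.array([rp, cp])
                else:
                    # retries stay in the lateral band, widen along the length
                    delta = min(2.5 * spacing, 2.0 + 0.5 * attempt)
                    p = np.array(
                        [
                            r_center + rng.uniform(-half_band, half_band),
                            cp + rng.uniform(-delta, delta),
                        ]
                    )
            else:
                p = np.array(
                    [rng.uniform(0, area_h), rng.uniform(0, area_w)]
                )
            half_r, half_c = _seed_half_extents(seed_axes_px, angle)
            if ok_placement(i, p, half_r, half_c) and ok_separation(p, half_r, half_c):
                centers.append(p)
                angles.append(angle)
                grid_index.setdefault(
                    (int(p[0] // cell), int(p[1] // cell)), []
                ).append((p[0], p[1], half_r, half_c))
                placed = True
                break
        if not placed:
            raise ConfigError(
                f"could not place seed {i} after {max_tries} tries; "
                "density too high for non-touching placement"
            )
    return np.array(centers).reshape(-1, 2), np.array(angles)


def render(
    plan: GridPlan | None = None,
    n_seeds: int | None = None,
    method: str = "broadcast",
    *,
    density_g: float | None = None,
    scale_px_per_mm: float = DEFAULT_SCALE_PX_PER_MM,
    border_px: int = 30,
    margin_px: int = 20,
    noise_sigma: float = 0.0,
    seed_axes_px: tuple[float, float] = (8.0, 3.0),
    jitter: float | None = None,
    straddle_frac: float = 0.0,
    seed: int = 0,
) -> TrayScene:
    """Render one tray scene and its full ground-truth manifest.

    The image layout, outside in: dark margin, bright border band of
    ``border_px``, and the soil-colored detection area holding the seeds.
    With ``noise_sigma=0`` the rendering is two-level and noiseless, so
    Otsu binarization recovers the drawn foreground mask exactly.
    Bit-reproducible for a fixed ``seed``.
    """
    if plan is None:
        if density_g is None:
            raise ConfigError("render needs a plan or a density")
        plan = build_grid_plan(SowingSpec(density_g))
    if n_seeds is None:
        n_seeds = (
            expected_seed_count(density_g)
            if density_g is not None
            else plan.expected_seeds_per_tray
        )
    rng = np.random.default_rng(seed)
    area_h = int(round(plan.tray.inner_width_mm * scale_px_per_mm))
    area_w = int(round(plan.tray.inner_length_mm * scale_px_per_mm))
    tile_h = area_h / plan.rows
    tile_w = area_w / plan.cols
    if seed_axes_px[0] > max(tile_h, tile_w) or seed_axes_px[1] > min(tile_h, tile_w):
        import warnings

        warnings.warn("seed ellipse larger than a tile; rendering anyway")

    off = margin_px + border_px  # top-left corner of the detection area
    h = area_h + 2 * off
    w = area_w + 2 * off
    img = np.zeros((h, w), dtype=float)
    img[margin_px:-margin_px, margin_px:-margin_px] = BORDER_LEVEL
    soil = np.full((area_h, area_w), float(SOIL_LEVEL))
    if noise_sigma > 0:
        soil += rng.normal(0, noise_sigma, size=soil.shape)
    img[off : off + area_h, off : off + area_w] = soil

    centers, angles = sample_positions(
        plan,
        n_seeds,
        method,
        jitter=jitter,
        seed=int(rng.integers(2**31 - 1)),
        scale_px_per_mm=scale_px_per_mm,
        seed_axes_px=seed_axes_px,
        straddle_frac=straddle_frac,
    )

    area = DetectionArea(row_lo=off, row_hi=off + area_h, col_lo=off, col_hi=off + area_w)
    tiles = segment_tiles(area, plan.rows, plan.cols)
    manifest = []
    for (r, c), angle in zip(centers, angles):
        rr, cc = draw_ellipse(
            r + off,
            c + off,
            seed_axes_px[0] / 2.0,
            seed_axes_px[1] / 2.0,
            shape=img.shape,
            rotation=angle,
        )
        img[rr, cc] = SEED_LEVEL
        bbox = (int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1)
        det = Detection(
            bbox=BBox.from_corners(bbox[1], bbox[0], bbox[3], bbox[2], frame="tray_px")
        )
        grid = assign_to_grid(det, tiles)
        manifest.append(
            SeedRecord(
                center_rc=(r + off, c + off),
                axes_px=tuple(seed_axes_px),
                angle_rad=float(angle),
                bbox_px=bbox,
                grid=grid,
            )
        )
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return TrayScene(
        image=img,
        manifest=manifest,
        plan=plan,
        area=area,
        tiles=tiles,
        method=method,
        density_g=density_g,
        seed=seed,
    )


def apply_perspective(
    image: np.ndarray,
    margin_px: int,
    max_tilt_deg: float = 5.0,
    seed: int = 0,
):
    """Warp a rendered tray with a small random homography.

    Emulates a hand-held overhead photograph that is not perfectly
    fronto-parallel: each image corner is displaced by up to
    ``tan(max_tilt_deg)`` of the image size.  Returns ``(warped_image,
    quad)`` where ``quad`` holds the tray outline's four outer corners
    (clockwise from top-left, ``(row, col)``) in the warped frame — the
    ground truth for corner extraction and rectification.
    """
    from skimage.transform import ProjectiveTransform, warp

    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    amp = math.tan(math.radians(max_tilt_deg))
    src = np.array([[0, 0], [0, w - 1], [h - 1, w - 1], [h - 1, 0]], dtype=float)
    dst = src + rng.uniform(-amp, amp, size=(4, 2)) * np.array([h, w])
    dst -= dst.min(axis=0)
    # estimate in (x, y) = (col, row)
    tform = ProjectiveTransform.from_estimate(src[:, ::-1], dst[:, ::-1])
    if not tform:
        raise ConfigError("could not estimate perspective transform")
    out_shape = tuple(np.ceil(dst.max(axis=0)).astype(int) + 1)
    warped = warp(
        np.asarray(image, dtype=float),
        tform.inverse,
        output_shape=out_shape,
        order=1,
        preserve_range=True,
    ).astype(image.dtype)
    tray_outline = np.array(
        [
            [margin_px, margin_px],
            [margin_px, w - 1 - margin_px],
            [h - 1 - margin_px, w - 1 - margin_px],
            [h - 1 - margin_px, margin_px],
        ],
        dtype=float,
    )
    quad = tform(tray_outline[:, ::-1])[:, ::-1]
    return warped, quad


def make_benchmark(seed: int = 0, **render_kwargs):
    """Render the nine sowing modes (3 densities x 3 methods).

    Returns ``(scenes, truth_table)``: one scene per mode with the density's
    expected seed count, and a DataFrame of manifest-derived uniformity
    statistics (density, method, grids, seeds, qualification and empty-grid
    rates).
    """
    from .grid_plan import SOWING_METHODS

    scenes = []
    rows = []
    rng = np.random.default_rng(seed)
    for density in (50, 60, 70):
        for method in SOWING_METHODS:
            scene = render(
                density_g=density,
                method=method,
                seed=int(rng.integers(2**31 - 1)),
                **render_kwargs,
            )
            scenes.append(scene)
            rep = report(scene.truth_occupancy())
            rows.append(
                {
                    "density_g": density,
                    "method": method,
                    "n_grids": rep.n_grids,
                    "n_seeds": rep.n_seeds,
                    "qualification_rate_pct": rep.qualification_rate_pct,
                    "empty_grid_rate_pct": rep.empty_grid_rate_pct,
                }
            )
    return scenes, pd.DataFrame(rows)
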