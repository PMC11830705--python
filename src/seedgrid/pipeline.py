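"""End-to-end orchestration: image -> tiles -> detections -> uniformity report.

The stages follow the evaluation workflow for a sown tray photograph:
binarize, (optionally) extract and rectify the tray outline, localize the
detection area by projection profiles, cut it into the planned seed grids,
detect seeds per tile, merge cross-tile fragments, assign seeds to grids,
and report qualification and empty-grid rates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .detector.blob import DEFAULT_MIN_AREA_PX, blob_detect
from .errors import ConfigError, DataError
from .grid_plan import DEFAULT_ROWS, DEFAULT_TGW_G, GridPlan, SowingSpec, build_grid_plan
from .preprocess import (
    affine_correct,
    binarize,
    extract_tray_quadrilateral,
    locate_detection_area,
    segment_tiles,
)
from .uniformity import (
    UniformityReport,
    globalize,
    merge_cross_tile,
    occupancy,
    report,
)

log = logging.getLogger("seedgrid")


@dataclass
class RunConfig:
    """Everything one evaluation run depends on; serialized beside outputs."""

    input_path: str | None = None
    out_dir: str | None = None
    density_g: float = 50.0
    thousand_grain_weight_g: float = DEFAULT_TGW_G
    method: str = "broadcast"
    rows: int = DEFAULT_ROWS
    backend: str = "blob"
    min_area_px: int = DEFAULT_MIN_AREA_PX
    iou_threshold: float = 0.3
    edge_gap_px: float = 2.0
    binarize_method: str = "otsu"
    binarize_threshold: float | None = None
    correct_perspective: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.backend != "blob":
            raise ConfigError(
                f"unknown detector backend {self.backend!r}; "
                "the neural backend requires a trained weight set"
            )
        if self.rows < 1:
            raise ConfigError("rows must be >= 1")
        # raises ConfigError on bad density / method
        SowingSpec(self.density_g, self.thousand_grain_weight_g, self.method)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Report plus per-stage counts and intermediate artifacts."""

    report: UniformityReport
    plan: GridPlan
    n_tiles: int
    n_raw_detections: int
    n_merged_detections: int
    counts: np.ndarray = field(repr=False, default=None)


def evaluate_image(
    image: np.ndarray, config: RunConfig, plan: GridPlan | None = None
) -> PipelineResult:
    """Run the full evaluation on an in-memory grayscale/RGB tray image.

    The grid plan is derived from the configured density unless an explicit
    ``plan`` is given (e.g. for reduced-scale scenes).
    """
    config.validate()
    t0 = time.perf_counter()
    if plan is None:
        plan = build_grid_plan(
            SowingSpec(config.density_g, config.thousand_grain_weight_g, config.method),
            rows=config.rows,
        )
    binary = binarize(image, config.binarize_method, config.binarize_threshold)
    if config.correct_perspective:
        quad = extract_tray_quadrilateral(binary)
        h = int(round(np.linalg.norm(quad[3] - quad[0])))
        w = int(round(np.linalg.norm(quad[1] - quad[0])))
        image = affine_correct(image, quad, (h, w))
        binary = binarize(image, config.binarize_method, config.binarize_threshold)
    area = locate_detection_area(binary)
    tiles = segment_tiles(area, plan.rows, plan.cols)
    log.info("detection area %dx%d px, %d tiles", area.height, area.width, len(tiles))

    raw = []
    for tile in tiles:
        for det in blob_detect(tile.crop(binary), config.min_area_px):
            raw.append(
                dataclasses.replace(det, source_tile=(tile.grid_row, tile.grid_col))
            )
    global_dets = globalize(raw, tiles)
    merged = merge_cross_tile(global_dets, config.iou_threshold, config.edge_gap_px)
    occ = occupancy(merged, tiles, plan)
    rep = report(occ)
    log.info(
        "%d raw detections -> %d seeds in %.2f s; qualification %.2f%%",
        len(raw), len(merged), time.perf_counter() - t0, rep.qualification_rate_pct,
    )
    return PipelineResult(
        report=rep,
        plan=plan,
        n_tiles=len(tiles),
        n_raw_detections=len(raw),
        n_merged_detections=len(merged),
        counts=occ.counts,
    )


def run_pipeline(config: RunConfig, plan: GridPlan | None = None) -> UniformityReport:
    """Evaluate the configured input image and write report artifacts.

    Writes ``report.json``, ``report.csv`` and the exact ``config.yaml``
    into ``config.out_dir`` (if set).  Deterministic: the same config and
    seed produce byte-identical reports.
    """
    config.validate()
    if config.input_path is None:
        raise ConfigError("run_pipeline needs an input image path")
    path = Path(config.input_path)
    if not path.exists():
        raise DataError(f"input image not found: {path}")
    try:
        image = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the stage and path
        raise DataError(f"preprocess failed for {path}: {exc}") from exc
    result = evaluate_image(np.asarray(image), config, plan=plan)
    if config.out_dir:
        write_report(result, config, Path(config.out_dir))
    return result.report


def write_report(result: PipelineResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rep = result.report
    (out_dir / "report.json").write_text(
        json.dumps(
            {
                "report": rep.to_dict(),
                "plan": result.plan.to_dict(),
                "stage_counts": {
                    "tiles": result.n_tiles,
                    "raw_detections": result.n_raw_detections,
                    "merged_detections": result.n_merged_detections,
                },
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    (out_dir / "report.csv").write_text(
        "density_g,method,n_grids,n_seeds,qualification_rate_pct,empty_grid_rate_pct\n"
        f"{config.density_g},{config.method},{rep.n_grids},{rep.n_seeds},"
        f"{rep.qualification_rate_pct},{rep.empty_grid_rate_pct}\n"
    )
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
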