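"""Globalization, cross-tile merging, grid ownership, uniformity statistics.

Per-tile detections are mapped into the tray pixel frame, fragments of seeds
cut by tile boundaries are merged back into single detections, each seed is
assigned to the seed grid its bounding box covers most (ties to the smallest
``(row, col)``), and the per-grid counts yield the two headline statistics:

* qualification rate — percentage of grids holding 1-3 seeds (the agronomic
  target band for 2-2.5 seedlings per hill), and
* empty-grid rate — percentage of grids holding none.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .detector.losses import BBox, Detection
from .errors import ConfigError, DataError
from .grid_plan import GridPlan
from .preprocess import SeedGridTile


@dataclass(frozen=True)
class GridOccupancy:
    """Per-grid seed counts for one tray."""

    counts: np.ndarray  # rows x cols, non-negative ints
    plan: GridPlan | None = None

    @property
    def n_grids(self) -> int:
        return self.counts.size

    @property
    def n_seeds(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class UniformityReport:
    """Headline uniformity statistics of one tray."""

    qualification_rate_pct: float
    empty_grid_rate_pct: float
    count_histogram: dict[int, int]
    n_grids: int
    n_seeds: int

    def to_dict(self) -> dict:
        return {
            "qualification_rate_pct": self.qualification_rate_pct,
            "empty_grid_rate_pct": self.empty_grid_rate_pct,
            "count_histogram": {str(k): v for k, v in sorted(self.count_histogram.items())},
            "n_grids": self.n_grids,
            "n_seeds": self.n_seeds,
        }


def _tile_index(tiles: list[SeedGridTile]) -> dict[tuple[int, int], SeedGridTile]:
    return {(t.grid_row, t.grid_col): t for t in tiles}


def globalize(dets: list[Detection], tiles: list[SeedGridTile]) -> list[Detection]:
    """Map normalized tile-frame boxes into tray pixel coordinates.

    Each detection's ``source_tile`` selects its tile rectangle; the
    normalized center-size box is scaled and shifted accordingly.  Box x is
    the column axis and y the row axis.
    """
    index = _tile_index(tiles)
    out = []
    for det in dets:
        if det.source_tile is None or det.source_tile not in index:
            raise DataError(f"detection references missing tile {det.source_tile}")
        t = index[det.source_tile]
        box = det.bbox
        out.append(
            replace(
                det,
                bbox=BBox(
                    cx=t.col_lo + box.cx * t.width,
                    cy=t.row_lo + box.cy * t.height,
                    w=box.w * t.width,
                    h=box.h * t.height,
                    frame="tray_px",
                ),
            )
        )
    return out


def _boxes_mergeable(a: Detection, b: Detection, iou_threshold: float,
                     edge_gap_px: float) -> bool:
    from .detector.losses import iou as _iou

    if _iou(a.bbox, b.bbox) >= iou_threshold:
        return True
    if a.source_tile is None or b.source_tile is None:
        return False
    (ra, ca), (rb, cb) = a.source_tile, b.source_tile
    if abs(ra - rb) + abs(ca - cb) != 1:
        return False
    if ra == rb:  # horizontally adjacent: shared vertical boundary
        left, right = (a, b) if ca < cb else (b, a)
        gap = right.bbox.x_lo - left.bbox.x_hi
        overlap = min(a.bbox.y_hi, b.bbox.y_hi) - max(a.bbox.y_lo, b.bbox.y_lo)
    else:  # vertically adjacent: shared horizontal boundary
        top, bottom = (a, b) if ra < rb else (b, a)
        gap = bottom.bbox.y_lo - top.bbox.y_hi
        overlap = min(a.bbox.x_hi, b.bbox.x_hi) - max(a.bbox.x_lo, b.bbox.x_lo)
    return gap <= edge_gap_px and overlap > 0


def merge_cross_tile(
    dets: list[Detection],
    iou_threshold: float = 0.3,
    edge_gap_px: float = 2.0,
) -> list[Detection]:
    """Re-unite seed fragments produced by tile cutting.

    Two tray-frame detections merge when their boxes overlap with IoU at
    least ``iou_threshold``, or when they come from adjacent tiles, both
    abut the shared tile boundary within ``edge_gap_px``, and their
    projections on that boundary overlap.  Merging is transitive (connected
    components); each component becomes one detection with the union box,
    the maximum confidence, and no source tile.
    """
    n = len(dets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # candidate pruning: sort by x_lo, compare while x-intervals can touch
    order = sorted(range(n), key=lambda i: dets[i].bbox.x_lo)
    for ii, i in enumerate(order):
        for j in order[ii + 1 :]:
            if dets[j].bbox.x_lo > dets[i].bbox.x_hi + edge_gap_px:
                break
            if _boxes_mergeable(dets[i], dets[j], iou_threshold, edge_gap_px):
                parent[find(i)] = find(j)

    groups: dict[int, list[Detection]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(dets[i])
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        box = members[0].bbox
        for m in members[1:]:
            box = box.union_with(m.bbox)
        merged.append(
            Detection(
                bbox=box,
                confidence=max(m.confidence for m in members),
                class_id=members[0].class_id,
                source_tile=None,
            )
        )
    merged.sort(key=lambda d: (d.bbox.cy, d.bbox.cx))
    return merged


def _grid_cuts(tiles: list[SeedGridTile]) -> tuple[np.ndarray, np.ndarray]:
    rows = max(t.grid_row for t in tiles) + 1
    cols = max(t.grid_col for t in tiles) + 1
    index = _tile_index(tiles)
    if len(index) != rows * cols:
        raise ConfigError("tiles do not form a complete rows x cols grid")
    rcuts = np.array([index[(r, 0)].row_lo for r in range(rows)] + [index[(rows - 1, 0)].row_hi])
    ccuts = np.array([index[(0, c)].col_lo for c in range(cols)] + [index[(0, cols - 1)].col_hi])
    return rcuts, ccuts


def assign_to_grid(det: Detection, tiles: list[SeedGridTile]) -> tuple[int, int]:
    """Grid ownership of one tray-frame detection by largest covered area.

    Among the (up to four) grids the box intersects, the one covering the
    largest share of the box wins; exact ties go to the smallest
    ``(row, col)`` lexicographically, which is order-independent.
    """
    rcuts, ccuts = _grid_cuts(tiles)
    b = det.bbox
    if b.x_hi <= ccuts[0] or b.x_lo >= ccuts[-1] or b.y_hi <= rcuts[0] or b.y_lo >= rcuts[-1]:
        raise DataError("detection box lies fully outside the detection area")
    r_first = max(0, int(np.searchsorted(rcuts, b.y_lo, side="right")) - 1)
    r_last = min(len(rcuts) - 2, int(np.searchsorted(rcuts, b.y_hi, side="left")) - 1)
    c_first = max(0, int(np.searchsorted(ccuts, b.x_lo, side="right")) - 1)
    c_last = min(len(ccuts) - 2, int(np.searchsorted(ccuts, b.x_hi, side="left")) - 1)
    best = None
    for r in range(r_first, r_last + 1):
        for c in range(c_first, c_last + 1):
            w = min(b.x_hi, ccuts[c + 1]) - max(b.x_lo, ccuts[c])
            h = min(b.y_hi, rcuts[r + 1]) - max(b.y_lo, rcuts[r])
            if w <= 0 or h <= 0:
                continue
            area = w * h
            # strict inequality keeps the smallest (row, col) on ties
            if best is None or area > best[0] + 1e-9:
                best = (area, r, c)
    if best is None:
        raise DataError("detection box does not intersect any grid")
    return best[1], best[2]


def occupancy(
    dets: list[Detection],
    tiles: list[SeedGridTile],
    plan: GridPlan | None = None,
) -> GridOccupancy:
    """Per-grid seed counts from merged, globalized detections."""
    rows = max(t.grid_row for t in tiles) + 1
    cols = max(t.grid_col for t in tiles) + 1
    counts = np.zeros((rows, cols), dtype=int)
    for det in dets:
        r, c = assign_to_grid(det, tiles)
        counts[r, c] += 1
    return GridOccupancy(counts=counts, plan=plan)


def count_histogram(occ: GridOccupancy) -> dict[int, int]:
    values, freq = np.unique(occ.counts, return_counts=True)
    return {int(v): int(f) for v, f in zip(values, freq)}


def qualification_rate(occ: GridOccupancy) -> float:
    """Percentage of grids containing 1-3 seeds, rounded to 2 decimals."""
    if occ.n_grids == 0:
        raise DataError("occupancy has zero grids")
    ok = np.count_nonzero((occ.counts >= 1) & (occ.counts <= 3))
    return round(ok / occ.n_grids * 100.0, 2)


def empty_grid_rate(occ: GridOccupancy) -> float:
    """Percentage of grids containing no seed, rounded to 2 decimals."""
    if occ.n_grids == 0:
        raise DataError("occupancy has zero grids")
    return round(np.count_nonzero(occ.counts == 0) / occ.n_grids * 100.0, 2)


def miss_rate(n_annotated: int, n_detected: int) -> float:
    """Percentage of annotated seeds the detector failed to find."""
    if n_annotated <= 0:
        raise DataError("miss rate undefined for zero annotated seeds")
    if not 0 <= n_detected <= n_annotated:
        raise DataError("detected count must lie in [0, annotated]")
    return round((n_annotated - n_detected) / n_annotated * 100.0, 2)


def test_error(actual_rate: float, testing_rate: float) -> float:
    """Signed difference actual - testing qualification rate (pct points)."""
    for r in (actual_rate, testing_rate):
        if not 0.0 <= r <= 100.0:
            raise DataError(f"rate {r} outside [0, 100]")
    return round(actual_rate - testing_rate, 2)


def report(occ: GridOccupancy) -> UniformityReport:
    """Bundle the uniformity statistics of one tray."""
    return UniformityReport(
        qualification_rate_pct=qualification_rate(occ),
        empty_grid_rate_pct=empty_grid_rate(occ),
        count_histogram=count_histogram(occ),
        n_grids=occ.n_grids,
        n_seeds=occ.n_seeds,
    )
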