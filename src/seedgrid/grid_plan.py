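"""Seed-grid division of a blanket-seedling tray.

A blanket tray is an open cuboid nursery tray (inner cavity 25 x 280 x 580 mm
by default) in which rice seeds are sown as a continuous mat.  For uniformity
evaluation the mat is divided into virtual *seed grids*, each grid being the
unit seedling-taken area of a transplanter: 18 horizontal cutting strips (one
per seeder row) times a number of longitudinal cuts set by the transplanter's
seedling-feeding gear (integer millimetres, 8-18 mm range, 11 gears).

Given a sowing density (g/tray) and the variety's thousand-grain weight (g),
the expected seed count per tray follows, and the gear is chosen so that the
mean number of seeds per grid lands in the agronomic sweet spot of 2.7-2.9
seeds (which, at a 75-85 % germination rate, yields the 2-2.5 seedlings per
hill that precise transplanting targets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigError, NoFeasiblePlanError

#: transplanter longitudinal feed gears, integer mm
GEAR_RANGE_MM = range(8, 19)

#: agronomically suitable mean seeds per grid
DEFAULT_TARGET_RANGE = (2.7, 2.9)

#: seeder rows, hence horizontal strips per tray
DEFAULT_ROWS = 18

#: thousand-grain weight of the reference hybrid variety (Taifengyou 208), g
DEFAULT_TGW_G = 24.75

SOWING_METHODS = ("broadcast", "strip_no_ditch", "strip_ditch")


@dataclass(frozen=True)
class TrayGeometry:
    """Inner-cavity dimensions of a blanket-seedling tray, in mm."""

    inner_length_mm: float = 580.0
    inner_width_mm: float = 280.0
    depth_mm: float = 25.0

    def __post_init__(self):
        if min(self.inner_length_mm, self.inner_width_mm, self.depth_mm) <= 0:
            raise ConfigError("tray dimensions must be positive")
        if self.inner_length_mm < self.inner_width_mm:
            raise ConfigError("tray length must be >= width")


@dataclass(frozen=True)
class SowingSpec:
    """Sowing density, seed mass, and placement method for one tray."""

    density_g_per_tray: float
    thousand_grain_weight_g: float = DEFAULT_TGW_G
    method: str = "broadcast"

    def __post_init__(self):
        if self.density_g_per_tray <= 0:
            raise ConfigError("sowing density must be positive")
        if self.thousand_grain_weight_g <= 0:
            raise ConfigError("thousand-grain weight must be positive")
        if self.method not in SOWING_METHODS:
            raise ConfigError(
                f"unknown sowing method {self.method!r}; "
                f"expected one of {SOWING_METHODS}"
            )


@dataclass(frozen=True)
class GridPlan:
    """One tray's seed-grid division and its expected occupancy.

    ``rows`` horizontal strips by ``cols`` longitudinal cuts; ``gear_mm`` is
    the transplanter feed step that produced ``cols``.  ``grid_frame_mm`` is
    the physical (width, length) of one grid, i.e. the wire-frame cell used
    for manual ground-truth counting.
    """

    rows: int
    cols: int
    gear_mm: int
    horizontal_cut_mm: float
    expected_seeds_per_tray: int
    expected_seeds_per_grid: float
    grid_frame_mm: tuple[float, float]
    tray: TrayGeometry = field(default_factory=TrayGeometry)

    @property
    def n_grids(self) -> int:
        return self.rows * self.cols

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "n_grids": self.n_grids,
            "gear_mm": self.gear_mm,
            "horizontal_cut_mm": self.horizontal_cut_mm,
            "expected_seeds_per_tray": self.expected_seeds_per_tray,
            "expected_seeds_per_grid": self.expected_seeds_per_grid,
            "grid_frame_mm": list(self.grid_frame_mm),
        }


def _round_half_away(x: float) -> int:
    """Round half away from zero (2020.2 -> 2020, 0.5 -> 1)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def expected_seed_count(density_g: float, tgw_g: float = DEFAULT_TGW_G) -> int:
    """Expected seeds per tray from sown mass and thousand-grain weight.

    ``density_g / tgw_g * 1000`` rounded half away from zero; e.g. 50 g of a
    24.75 g/1000 variety gives 2020 seeds.
    """
    if density_g <= 0 or tgw_g <= 0:
        raise ConfigError("density and thousand-grain weight must be positive")
    return _round_half_away(density_g / tgw_g * 1000.0)


def select_longitudinal_gear(
    seed_count: int,
    tray: TrayGeometry | None = None,
    rows: int = DEFAULT_ROWS,
    target_range: tuple[float, float] = DEFAULT_TARGET_RANGE,
) -> tuple[int, int]:
    """Choose the feed gear whose grid count puts mean seeds/grid in range.

    For each integer gear ``g`` in 8-18 mm the tray length admits
    ``floor(inner_length / g)`` longitudinal cuts.  Returns ``(gear_mm,
    cols)`` for the gear whose mean ``seed_count / (rows * cols)`` lies in
    ``target_range``; among several feasible gears the one closest to the
    range midpoint wins (ties to the smaller gear).  Deterministic.

    Raises
    ------
    NoFeasiblePlanError
        If no gear is feasible; the error carries the per-gear means.
    """
    tray = tray or TrayGeometry()
    if seed_count <= 0:
        raise ConfigError("seed count must be positive")
    if rows < 1:
        raise ConfigError("rows must be >= 1")
    lo, hi = target_range
    mid = 0.5 * (lo + hi)

    means = {}
    feasible = []
    for g in GEAR_RANGE_MM:
        cols = int(tray.inner_length_mm // g)
        if cols < 1:
            continue
        mean = seed_count / (rows * cols)
        means[g] = mean
        if lo <= mean <= hi:
            feasible.append((abs(mean - mid), g, cols))
    if not feasible:
        detail = ", ".join(f"{g} mm -> {m:.3f}" for g, m in means.items())
        raise NoFeasiblePlanError(
            f"no feasible plan: no gear in 8-18 mm gives a mean of "
            f"{lo}-{hi} seeds/grid for {seed_count} seeds over {rows} rows "
            f"(per-gear means: {detail})",
            per_gear_means=means,
        )
    feasible.sort()
    _, gear, cols = feasible[0]
    return gear, cols


def build_grid_plan(
    spec: SowingSpec,
    tray: TrayGeometry | None = None,
    rows: int = DEFAULT_ROWS,
) -> GridPlan:
    """Full grid plan for one sowing specification.

    Reproduces the published division table: at 50/60/70 g per tray with a
    24.75 g thousand-grain weight the selected gears are 14/12/10 mm, giving
    18x41=738, 18x48=864 and 18x58=1044 grids with 2.74/2.81/2.71 expected
    seeds per grid and grid frames of 15.56x14.15, 15.56x12.08 and
    15.56x10.00 mm.
    """
    tray = tray or TrayGeometry()
    n_seeds = expected_seed_count(
        spec.density_g_per_tray, spec.thousand_grain_weight_g
    )
    gear, cols = select_longitudinal_gear(n_seeds, tray, rows)
    n_grids = rows * cols
    return GridPlan(
        rows=rows,
        cols=cols,
        gear_mm=gear,
        horizontal_cut_mm=round(tray.inner_width_mm / rows, 2),
        expected_seeds_per_tray=n_seeds,
        expected_seeds_per_grid=round(n_seeds / n_grids, 2),
        grid_frame_mm=(
            round(tray.inner_width_mm / rows, 2),
            round(tray.inner_length_mm / cols, 2),
        ),
        tray=tray,
    )
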