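"""Shared fixtures: plans and rendered scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from seedgrid.grid_plan import GridPlan, SowingSpec, TrayGeometry, build_grid_plan
from seedgrid.synthetic import make_benchmark, render


@pytest.fixture(scope="session")
def plan50() -> GridPlan:
    return build_grid_plan(SowingSpec(50))


@pytest.fixture(scope="session")
def small_plan() -> GridPlan:
    """A reduced 6x10 grid on a small tray, for fast property tests."""
    tray = TrayGeometry(inner_length_mm=240, inner_width_mm=140)
    return GridPlan(
        rows=6,
        cols=10,
        gear_mm=12,
        horizontal_cut_mm=round(140 / 6, 2),
        expected_seeds_per_tray=150,
        expected_seeds_per_grid=2.5,
        grid_frame_mm=(round(140 / 6, 2), 24.0),
        tray=tray,
    )


@pytest.fixture(scope="session")
def scene50(plan50):
    """One full-size noiseless broadcast tray at 50 g/tray."""
    return render(plan=plan50, density_g=50, method="broadcast", seed=1)


@pytest.fixture(scope="session")
def small_scene(small_plan):
    return render(plan=small_plan, n_seeds=150, method="broadcast", seed=2)


@pytest.fixture(scope="session")
def benchmark():
    """The nine sowing modes (3 densities x 3 methods) with ground truth."""
    return make_benchmark(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
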