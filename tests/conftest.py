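"""Shared fixtures: small synthetic worlds and cached scenario runs."""

from __future__ import annotations

import numpy as np
import pytest

import plumlite as pl


@pytest.fixture(scope="session")
def small_world():
    """2 countries x 9 cells x 3 crops."""
    return pl.generate_world(2, 9, 3, seed=1)


@pytest.fixture(scope="session")
def tiny_clusters(small_world):
    world, anchors = small_world
    cls = pl.cluster_country(world, anchors, "C00", k=2, seed=0)
    budget = pl.build_water_budget(world, anchors)
    from plumlite.country_optimiser import attach_water

    attach_water(cls, budget)
    return world, anchors, cls


@pytest.fixture(scope="session")
def short_run():
    """Cached 4-year scenario run on a tiny world (2 x 9 cells, 2 crops)."""
    cfg = pl.ScenarioConfig(start_year=2010, end_year=2013, seed=3)
    return pl.run_scenario(cfg, n_countries=2, cells_per_country=9, n_crops=2)


@pytest.fixture(scope="session")
def long_run():
    """Cached constant-drivers run to 2030 for stability auditing."""
    cfg = pl.ScenarioConfig(start_year=2010, end_year=2030, seed=3)
    return pl.run_scenario(cfg, n_countries=2, cells_per_country=9, n_crops=2)


@pytest.fixture(scope="session")
def surfaces_sample(small_world):
    """A handful of fitted yield surfaces from the small world."""
    world, anchors = small_world
    rng = np.random.default_rng(0)
    cells = rng.choice(world.n_cells, size=6, replace=False)
    out = []
    for c in cells:
        for lu in range(len(anchors.land_uses)):
            out.append((int(c), lu, pl.fit_surface(anchors, int(c), lu)))
    return anchors, out
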