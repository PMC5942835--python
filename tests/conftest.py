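"""Shared fixtures: tiny grids and clusters built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popgrid.clustering import Cluster
from popgrid.grid_io import PopulationGrid, RegionAttributeTable

BASELINE, FOLLOWUP = 2005, 2010


def grid_from_counts(baseline: dict, followup: dict | None = None,
                     years=(BASELINE, FOLLOWUP)) -> PopulationGrid:
    """Build a grid from ``{(col,row): (female, male)}`` maps per year."""
    rows = []
    for (c, r), (f, m) in baseline.items():
        rows.append((c, r, years[0], f, m))
    for (c, r), (f, m) in (followup or {}).items():
        rows.append((c, r, years[1], f, m))
    df = pd.DataFrame(rows, columns=["col", "row", "year", "female", "male"])
    return PopulationGrid(df, years=years)


def cluster_of(cells, cluster_id=1, year=BASELINE) -> Cluster:
    return Cluster(cluster_id, year, frozenset(cells))


def single_region_table(mean_age=44.0, tertiary=0.65, bound=1000) -> RegionAttributeTable:
    return RegionAttributeTable(pd.DataFrame([{
        "region_id": "R0", "mean_age": mean_age, "tertiary_fraction": tertiary,
        "col_min": -bound, "col_max": bound, "row_min": -bound, "row_max": bound,
    }]))


@pytest.fixture
def region_table():
    return single_region_table()


@pytest.fixture
def fig_example_grid():
    """A five-cell baseline cluster (10+20+30+40+50 inhabitants) whose
    footprint holds 10+15+60 at follow-up, with extra follow-up population
    outside the footprint that must be ignored."""
    baseline = {
        (0, 0): (5, 5),     # 10
        (1, 0): (10, 10),   # 20
        (2, 0): (15, 15),   # 30
        (0, 1): (20, 20),   # 40
        (1, 1): (25, 25),   # 50
    }
    followup = {
        (0, 0): (5, 5),     # 10
        (1, 0): (10, 5),    # 15
        (2, 0): (30, 30),   # 60
        (5, 5): (40, 40),   # outside the baseline footprint: ignored
    }
    return grid_from_counts(baseline, followup)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
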