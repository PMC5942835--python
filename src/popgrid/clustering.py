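"""City clustering: inhabited clusters as connected components of populated
cells under the von Neumann (4-neighbour) adjacency, and population
accounting inside fixed baseline footprints.

The dependent variable of the downstream regression is the follow-up
population *inside the baseline footprint*: clusters are identified at the
baseline year only, and later splits, merges or growth beyond the footprint
are deliberately ignored.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_io import PopulationGrid

logger = logging.getLogger(__name__)

#: von Neumann structuring element (no diagonal connectivity).
VON_NEUMANN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclasses.dataclass(frozen=True)
class Cluster:
    """A connected set of populated cells at a given year."""

    cluster_id: int
    year: object
    cells: frozenset

    @property
    def area(self) -> int:
        return len(self.cells)


def find_clusters(grid: PopulationGrid, year=None) -> list[Cluster]:
    """Connected components of populated cells (4-neighbour adjacency).

    Cluster ids are assigned in scanning order of each component's minimum
    cell under (row, col) ordering, starting at 1, so ids are stable across
    runs and input permutations.
    """
    if year is None:
        year = grid.baseline_year
    coords = grid.populated_coords(year)
    if not coords:
        return []
    cols = np.array([c for c, _ in coords])
    rows = np.array([r for _, r in coords])
    c0, r0 = cols.min(), rows.min()
    arr = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    arr[rows - r0, cols - c0] = True
    labels, n = ndimage.label(arr, structure=VON_NEUMANN)
    lab = labels[rows - r0, cols - c0]
    members: dict[int, list] = {}
    for (c, r), l in zip(coords, lab):
        members.setdefault(int(l), []).append((int(c), int(r)))
    # populated_coords is already in (row, col) scan order, so the first
    # member of each component is its minimum cell.
    ordered = sorted(members.values(), key=lambda cells: (cells[0][1], cells[0][0]))
    return [Cluster(i + 1, year, frozenset(cells)) for i, cells in enumerate(ordered)]


def count_clusters(grid: PopulationGrid, year) -> int:
    """Diagnostic cluster count at an arbitrary year (feeds nothing downstream)."""
    return len(find_clusters(grid, year))


def footprint_populations(clusters: Sequence[Cluster], grid: PopulationGrid,
                          baseline_year=None, followup_year=None) -> pd.DataFrame:
    """Baseline and follow-up populations inside each baseline footprint.

    ``n_baseline`` sums inhabitants over the cluster's cells at the baseline
    year, ``n_followup`` over the *same* cell set at the follow-up year;
    follow-up inhabitants outside every baseline footprint are ignored.
    """
    if baseline_year is None:
        baseline_year = grid.baseline_year
    if followup_year is None:
        followup_year = grid.followup_year
    base = grid.population_map(baseline_year)
    follow = grid.population_map(followup_year)
    records = []
    for cl in sorted(clusters, key=lambda c: c.cluster_id):
        nb = nf = 0
        for cell in cl.cells:
            if cell not in base:
                raise ValueError(
                    f"cluster {cl.cluster_id} cell {cell} is absent from the "
                    f"grid at baseline year {baseline_year}")
            f, m = base[cell]
            nb += f + m
            if cell in follow:
                f, m = follow[cell]
                nf += f + m
        records.append((cl.cluster_id, nb, nf))
    return pd.DataFrame(records, columns=["cluster_id", "n_baseline", "n_followup"])


def filter_min_area(clusters: Iterable[Cluster], min_cells: int = 10) -> list[Cluster]:
    """Keep clusters with at least `min_cells` cells.

    Small clusters are dropped because their geometry is dominated by the
    spatial discreteness of the grid.
    """
    if min_cells < 1:
        raise ValueError(f"min_cells must be >= 1, got {min_cells}")
    clusters = list(clusters)
    kept = [c for c in clusters if c.area >= min_cells]
    logger.info("filter_min_area(min_cells=%d): kept %d of %d clusters (dropped %d)",
                min_cells, len(kept), len(clusters), len(clusters) - len(kept))
    return kept


def export_membership(clusters: Iterable[Cluster], path) -> None:
    """Cluster membership CSV: cluster_id,col,row (deterministic order)."""
    rows = []
    for cl in sorted(clusters, key=lambda c: c.cluster_id):
        for col, row in sorted(cl.cells, key=lambda cr: (cr[1], cr[0])):
            rows.append((cl.cluster_id, col, row))
    pd.DataFrame(rows, columns=["cluster_id", "col", "row"]).to_csv(
        path, index=False, lineterminator="\n")
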