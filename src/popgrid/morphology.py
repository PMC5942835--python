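"""Per-cluster shape, distribution and demographic indices.

All distances are Euclidean between cell centers, in cell-side units.
The indices:

* ``roundness`` — area S over the area of the circle whose diameter is the
  longest inter-cell-center distance; close to a disc => large.
* ``irregularity`` — 2·log L / log S with L the perimeter (number of unit
  cell edges exposed to non-member cells, holes included).  Via the scaling
  relation S = L^(2/Irregularity) this is a perimeter-based fractal-dimension
  proxy; base-invariant (natural log used internally).
* ``cl`` (characteristic length) — expected distance between two uniformly
  random inhabitants of the cluster, divided by sqrt(S) to decorrelate from
  area; small when population concentrates at the cluster centre.
* ``heterogeneity`` — coefficient of variation (sample SD / mean) of the
  per-cell inhabitant counts.
* ``gender`` — fraction of female inhabitants.
* ``age`` / ``tertiary`` — joined from a region table at the cluster's
  closeness-central cell.

Functions that are undefined for degenerate clusters (single cell, or fewer
than two inhabitants) return NaN; :func:`build_feature_table` turns any NaN
into a hard error, which cannot occur once the minimum-area filter (>= 10
cells) has been applied.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform

from .clustering import Cluster, footprint_populations
from .grid_io import PopulationGrid, RegionAttributeTable

#: Column order of the exported feature table.
FEATURE_COLUMNS = (
    "cluster_id", "n_baseline", "n_followup", "S", "density", "L",
    "roundness", "irregularity", "cl", "heterogeneity", "gender",
    "age", "tertiary",
)

#: Above this cell count the diameter search switches to the convex hull.
_BRUTE_FORCE_LIMIT = 2000


def _cells(cluster) -> list[tuple[int, int]]:
    cells = cluster.cells if isinstance(cluster, Cluster) else cluster
    return sorted(cells, key=lambda cr: (cr[1], cr[0]))


def _coords(cluster) -> np.ndarray:
    return np.asarray(_cells(cluster), dtype=float)


def longest_pairwise_distance(cluster) -> float:
    """Longest Euclidean distance between member cell centers.

    Brute force over all pairs for small clusters; convex-hull vertices
    otherwise (the diameter is attained on the hull).  A single-cell cluster
    is degenerate and yields 0.
    """
    pts = _coords(cluster)
    if len(pts) < 2:
        return 0.0
    if len(pts) > _BRUTE_FORCE_LIMIT:
        pts = pts[ConvexHull(pts).vertices]
    return float(pdist(pts).max())


def roundness(cluster) -> float:
    """S / (pi * (d_max / 2)^2); NaN for a single-cell cluster."""
    pts = _coords(cluster)
    s = len(pts)
    if s < 2:
        return math.nan
    d = longest_pairwise_distance(cluster)
    return s / (math.pi * (d / 2.0) ** 2)


def perimeter(cluster) -> int:
    """Number of unit cell edges adjacent to a non-member cell.

    Counts the outer boundary and any interior-hole boundaries: every cell
    contributes four edges and each side-sharing member pair hides two.
    """
    cells = set(_cells(cluster))
    adjacent = sum(1 for (c, r) in cells if (c + 1, r) in cells) \
        + sum(1 for (c, r) in cells if (c, r + 1) in cells)
    return 4 * len(cells) - 2 * adjacent


def irregularity(cluster) -> float:
    """2 log L / log S (base-invariant); NaN when S = 1."""
    s = len(_cells(cluster))
    if s < 2:
        return math.nan
    return 2.0 * math.log(perimeter(cluster)) / math.log(s)


def _member_counts(cluster, grid: PopulationGrid, year) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(coords, female, male) arrays for member cells in deterministic order."""
    pmap = grid.population_map(year)
    cells = _cells(cluster)
    fem = np.zeros(len(cells), dtype=np.int64)
    male = np.zeros(len(cells), dtype=np.int64)
    for i, cell in enumerate(cells):
        if cell in pmap:
            fem[i], male[i] = pmap[cell]
    return np.asarray(cells, dtype=float), fem, male


def characteristic_length(cluster, grid: PopulationGrid, year=None) -> float:
    """Expected inhabitant-pair distance divided by sqrt(S).

    CL = [sum_{i<j} n_i n_j d_ij] / C(n, 2) / sqrt(S) with n the cluster
    population; same-cell pairs contribute distance 0 and are covered by the
    C(n, 2) denominator.  NaN when the cluster has fewer than 2 inhabitants.
    """
    if year is None:
        year = grid.baseline_year
    pts, fem, male = _member_counts(cluster, grid, year)
    n_cell = (fem + male).astype(float)
    n = n_cell.sum()
    if n < 2:
        return math.nan
    if len(pts) == 1:
        return 0.0
    dmat = squareform(pdist(pts))
    weighted = 0.5 * float(n_cell @ dmat @ n_cell)  # sum over unordered cell pairs
    pairs = n * (n - 1) / 2.0
    return weighted / pairs / math.sqrt(len(pts))


def heterogeneity(cluster, grid: PopulationGrid, year=None) -> float:
    """Coefficient of variation (sample SD, divisor S-1) of per-cell counts."""
    if year is None:
        year = grid.baseline_year
    _, fem, male = _member_counts(cluster, grid, year)
    counts = (fem + male).astype(float)
    if len(counts) < 2:
        return math.nan
    return float(np.std(counts, ddof=1) / np.mean(counts))


def gender_fraction(cluster, grid: PopulationGrid, year=None) -> float:
    """Fraction of female inhabitants among the cluster's population."""
    if year is None:
        year = grid.baseline_year
    _, fem, male = _member_counts(cluster, grid, year)
    total = int(fem.sum() + male.sum())
    if total == 0:
        raise ValueError("gender fraction undefined for zero population")
    return float(fem.sum()) / total


def central_cell(cluster) -> tuple[float, float]:
    """Center of the member cell with the largest closeness centrality.

    The cluster is viewed as an unweighted graph whose nodes are cells and
    whose edges join side-sharing cells; closeness is (number of other
    nodes) / (sum of shortest-path lengths), so the argmax is the cell with
    the smallest total graph distance.  Tied cells are averaged, which may
    yield a fractional coordinate.
    """
    cells = _cells(cluster)
    if len(cells) == 1:
        return (float(cells[0][0]), float(cells[0][1]))
    # closeness is translation-invariant: memoize on the normalized shape
    mc = min(c for c, _ in cells)
    mr = min(r for _, r in cells)
    oc, orow = _central_offset(frozenset((c - mc, r - mr) for c, r in cells))
    return (oc + mc, orow + mr)


@lru_cache(maxsize=20000)
def _central_offset(shape: frozenset) -> tuple[float, float]:
    cells = sorted(shape, key=lambda cr: (cr[1], cr[0]))
    if len(cells) <= 96:  # plain BFS beats sparse-graph setup on small shapes
        return _central_offset_bfs(cells, shape)
    pts = np.asarray(cells, dtype=np.int64)
    n = len(cells)
    # encode (col,row) as scalars and find side-sharing pairs by searchsorted
    rmin = pts[:, 1].min()
    span = pts[:, 1].max() - rmin + 2
    keys = pts[:, 0] * span + (pts[:, 1] - rmin)
    order = np.argsort(keys)
    skeys = keys[order]
    rows_l, cols_l = [], []
    for enc in (keys + span, keys + 1):  # east and north neighbours
        pos = np.searchsorted(skeys, enc)
        pos_ok = pos < n
        hit = np.flatnonzero(pos_ok)
        hit = hit[skeys[pos[hit]] == enc[hit]]
        i = hit
        j = order[pos[hit]]
        rows_l.append(np.concatenate([i, j]))
        cols_l.append(np.concatenate([j, i]))
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    dist = shortest_path(graph, method="D", unweighted=True, directed=False)
    if np.isinf(dist).any():
        raise ValueError("cluster is not connected")
    totals = dist.sum(axis=1)  # integer-valued, exact in float
    best = totals.min()
    tied = pts[totals == best].astype(float)
    return (float(tied[:, 0].mean()), float(tied[:, 1].mean()))


def _central_offset_bfs(cells: list, cellset) -> tuple[float, float]:
    adjacency = {}
    for (c, r) in cells:
        adjacency[(c, r)] = [nb for nb in ((c + 1, r), (c - 1, r), (c, r + 1), (c, r - 1))
                             if nb in cellset]
    n = len(cells)
    best = None
    tied = []
    for start in cells:
        seen = {start: 0}
        queue = [start]
        total = 0
        while queue:
            nxt = []
            for cell in queue:
                d = seen[cell] + 1
                for nb in adjacency[cell]:
                    if nb not in seen:
                        seen[nb] = d
                        total += d
                        nxt.append(nb)
            queue = nxt
        if len(seen) != n:
            raise ValueError("cluster is not connected")
        if best is None or total < best:
            best = total
            tied = [start]
        elif total == best:
            tied.append(start)
    return (sum(c for c, _ in tied) / len(tied), sum(r for _, r in tied) / len(tied))


def assign_region_attributes(cluster, region_table: RegionAttributeTable) -> tuple[float, float]:
    """(mean_age, tertiary_fraction) of the region containing the central cell."""
    col, row = central_cell(cluster)
    return region_table.lookup_attributes(col, row)


def build_feature_table(clusters: Iterable[Cluster], grid: PopulationGrid,
                        region_table: RegionAttributeTable,
                        baseline_year=None, followup_year=None) -> pd.DataFrame:
    """One complete feature row per cluster (columns :data:`FEATURE_COLUMNS`).

    Log transforms are *not* applied here; that is the inference module's
    job.  Any undefined (NaN) index raises, which cannot happen for clusters
    passing the minimum-area filter.
    """
    clusters = sorted(clusters, key=lambda c: c.cluster_id)
    year = baseline_year if baseline_year is not None else grid.baseline_year
    fyear = followup_year if followup_year is not None else grid.followup_year
    base = grid.population_map(year)
    follow = grid.population_map(fyear)
    rows = []
    for clus in clusters:
        cells = _cells(clus)
        cellset = clus.cells if isinstance(clus.cells, (set, frozenset)) else set(cells)
        s = len(cells)
        fem = np.empty(s, dtype=np.int64)
        male = np.empty(s, dtype=np.int64)
        nf = 0
        for i, cell in enumerate(cells):
            if cell not in base:
                raise ValueError(
                    f"cluster {clus.cluster_id} cell {cell} is absent from the "
                    f"grid at baseline year {year}")
            fem[i], male[i] = base[cell]
            if cell in follow:
                ff, fm = follow[cell]
                nf += ff + fm
        counts = fem + male
        nb = int(counts.sum())
        pts = np.asarray(cells, dtype=float)
        if s > _BRUTE_FORCE_LIMIT:
            dmax = float(pdist(pts[ConvexHull(pts).vertices]).max())
            dmat = squareform(pdist(pts))
        else:
            dvec = pdist(pts)
            dmax = float(dvec.max()) if len(dvec) else 0.0
            dmat = squareform(dvec)
        adjacent = sum(1 for (c, r) in cells if (c + 1, r) in cellset) \
            + sum(1 for (c, r) in cells if (c, r + 1) in cellset)
        lperim = 4 * s - 2 * adjacent
        cfl = counts.astype(float)
        pairs = nb * (nb - 1) / 2.0
        clval = (0.5 * float(cfl @ dmat @ cfl) / pairs / math.sqrt(s)
                 if nb >= 2 else math.nan)
        cc, cr = central_cell(clus)
        age, tertiary = region_table.lookup_attributes(cc, cr)
        row = {
            "cluster_id": clus.cluster_id,
            "n_baseline": nb,
            "n_followup": nf,
            "S": s,
            "density": nb / s,
            "L": lperim,
            "roundness": s / (math.pi * (dmax / 2.0) ** 2) if s >= 2 else math.nan,
            "irregularity": (2.0 * math.log(lperim) / math.log(s)
                             if s >= 2 else math.nan),
            "cl": clval,
            "heterogeneity": (float(np.std(cfl, ddof=1) / np.mean(cfl))
                              if s >= 2 else math.nan),
            "gender": float(fem.sum()) / nb,
            "age": age,
            "tertiary": tertiary,
        }
        for key in ("roundness", "irregularity", "cl", "heterogeneity"):
            if math.isnan(row[key]):
                raise ValueError(
                    f"feature {key!r} undefined for cluster {clus.cluster_id} "
                    f"(S={s}, n_baseline={nb}); apply the minimum-area filter first")
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def write_feature_table(features: pd.DataFrame, path) -> None:
    features[list(FEATURE_COLUMNS)].to_csv(path, index=False, lineterminator="\n")
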