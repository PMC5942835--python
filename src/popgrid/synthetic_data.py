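"""Synthetic population grids with known generating parameters.

The generator emulates the statistical structure the analysis assumes:
connected clusters spanning compact-to-line-like shapes (stochastic
Eden-style growth with an elongation bias), heavy-tailed cluster areas and
populations (truncated Pareto areas, lognormal densities), within-cluster
population concentration decaying from the closeness-central cell,
region-level age and tertiary-industry attributes, and follow-up counts
drawn from the NB2 offset model with a known coefficient vector — so every
pipeline stage is testable without any external data and parameter-recovery
experiments have a ground truth.

Default parameters are matched to observed national-census scales:
small mixed-sign generating coefficients on those covariate scales,
dispersion theta = 5, areas at least 10 cells with a Pareto tail,
density lognormal with median about 33 inhabitants/cell, gender fraction
0.515, region mean ages around 44.6 years and tertiary fractions around
0.653.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import pandas as pd

from . import morphology
from .clustering import filter_min_area, find_clusters
from .grid_io import PopulationGrid, RegionAttributeTable
from .inference import COVARIATES, build_model_matrix

#: Default generating coefficients for the NB2 offset model (log link;
#: "const" is the intercept): small effects of mixed sign, on the scale
#: observed in national gridded-census cluster analyses.
DEFAULT_BETA = {
    "const": -0.0146,
    "log_area": 0.0113,
    "log_density": 0.0227,
    "roundness": 0.0040,
    "irregularity": -0.0327,
    "cl": -0.0362,
    "heterogeneity": -0.0007,
    "gender": -0.0433,
    "age": -0.0024,
    "tertiary": -0.0098,
}


@dataclasses.dataclass
class SyntheticConfig:
    """Knobs of the synthetic-grid generator (seed mandatory)."""

    seed: int
    n_clusters: int = 2000
    area_exponent: float = 1.5     # Pareto tail exponent of cluster areas
    area_min: int = 10
    area_max: int = 300
    elongation: float = 0.8        # per-cluster elongation ~ U(0, elongation)
    concentration: float = 0.3     # distance-decay rate from the central cell
    heterogeneity_knob: float = 0.5  # lognormal sigma of cell-weight noise
    gender_mean: float = 0.515
    density_log_mean: float = 3.5  # lognormal log-mean of inhabitants/cell
    density_log_sd: float = 0.98
    n_regions: int = 8
    age_mean: float = 44.6
    age_sd: float = 1.24
    tertiary_mean: float = 0.653
    tertiary_sd: float = 0.045
    beta: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_BETA))
    theta: float = 5.0
    baseline_year: int = 2005
    followup_year: int = 2010
    buffer: int = 2                # empty cells between cluster bounding boxes

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0.0 <= self.elongation <= 1.0:
            raise ValueError("elongation must be in [0, 1]")
        if self.concentration < 0 or self.heterogeneity_knob < 0:
            raise ValueError("concentration and heterogeneity_knob must be >= 0")
        if not 0.0 <= self.gender_mean <= 1.0:
            raise ValueError("gender_mean must be in [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.area_min < 1 or self.area_max < self.area_min:
            raise ValueError("need 1 <= area_min <= area_max")
        if self.buffer < 1:
            raise ValueError("buffer must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated grid."""

    beta: dict
    theta: float
    seed: int
    features: pd.DataFrame        # realized per-cluster features
    config: SyntheticConfig

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta,
            "theta": self.theta,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "features": self.features.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# shapes

_NEIGHBOURS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def generate_shape(area: int, elongation: float, rng: np.random.Generator) -> set:
    """A connected polyomino of `area` cells grown from a single seed cell.

    ``elongation = 1`` returns the 1 x area straight line exactly;
    ``elongation = 0`` is uniform Eden growth (compact, blob-like).  In
    between, each growth step extends the horizontal extremes of the shape
    with probability `elongation`, interpolating between the two regimes.
    """
    if area < 1:
        raise ValueError("area must be >= 1")
    if elongation >= 1.0:
        return {(c, 0) for c in range(area)}
    cells = {(0, 0)}
    frontier = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    fset = set(frontier)
    col_sum = 0.0
    directed = rng.random(area - 1) < elongation if elongation > 0.0 else None
    picks = rng.random(area - 1)
    for step in range(area - 1):
        if directed is not None and directed[step]:
            cbar = col_sum / len(cells)
            best = -1.0
            pool = []
            for i, (c, _) in enumerate(frontier):
                d = c - cbar if c >= cbar else cbar - c
                if d > best:
                    best = d
                    pool = [i]
                elif d == best:
                    pool.append(i)
            idx = pool[int(picks[step] * len(pool))]
        else:
            idx = int(picks[step] * len(frontier))
        cell = frontier.pop(idx)
        fset.discard(cell)
        cells.add(cell)
        col_sum += cell[0]
        c0, r0 = cell
        for nb in ((c0 + 1, r0), (c0 - 1, r0), (c0, r0 + 1), (c0, r0 - 1)):
            if nb not in cells and nb not in fset:
                frontier.append(nb)
                fset.add(nb)
    return cells


# ---------------------------------------------------------------------------
# populations

def allocate_baseline_population(shape, total: int, concentration: float,
                                 heterogeneity_knob: float, gender_mean: float,
                                 rng: np.random.Generator) -> pd.DataFrame:
    """Distribute `total` inhabitants over the cells of `shape`.

    Every cell receives at least one inhabitant (the cluster definition
    requires populated cells); the remaining ``total - S`` are multinomial
    with weights decaying exponentially with distance from the
    closeness-central cell at rate `concentration`, times lognormal noise
    of sigma `heterogeneity_knob`.  Female counts are binomial with mean
    `gender_mean` per cell.
    """
    coords, female, male = _allocate_arrays(
        shape, total, concentration, heterogeneity_knob, gender_mean, rng)
    return pd.DataFrame({
        "col": coords[:, 0], "row": coords[:, 1],
        "female": female, "male": male,
    })


def _allocate_arrays(shape, total, concentration, heterogeneity_knob,
                     gender_mean, rng):
    cells = sorted(shape, key=lambda cr: (cr[1], cr[0]))
    s = len(cells)
    if total < s:
        raise ValueError(f"total ({total}) must be >= number of cells ({s})")
    coords = np.asarray(cells, dtype=np.int64)
    cc, cr = morphology.central_cell(frozenset(cells))
    dist = np.hypot(coords[:, 0] - cc, coords[:, 1] - cr)
    logw = -concentration * dist
    if heterogeneity_knob > 0:
        logw = logw + rng.normal(0.0, heterogeneity_knob, s)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    counts = 1 + rng.multinomial(total - s, w)
    female = rng.binomial(counts, gender_mean)
    return coords, female, counts - female


def simulate_followup(features: pd.DataFrame, beta: dict, theta: float,
                      rng: np.random.Generator, interactions: dict | None = None) -> np.ndarray:
    """Draw follow-up counts from the NB2 offset model.

    mu_c = n_baseline * exp(beta_0 + sum_i beta_i X_ic [+ interaction terms]);
    interaction products, if any, are formed from mean-centered covariates.
    Counts are drawn through the exact gamma–Poisson mixture representation
    of the NB2 law.
    """
    X = build_model_matrix(features, center=False).covariates
    eta = np.full(len(X), float(beta.get("const", 0.0)))
    for cov in COVARIATES:
        b = float(beta.get(cov, 0.0))
        if b != 0.0:
            eta += b * X[cov].to_numpy()
    if interactions:
        Xc = X - X.mean()
        for (a, b_), coef in interactions.items():
            eta += float(coef) * (Xc[a] * Xc[b_]).to_numpy()
    mu = features["n_baseline"].to_numpy(dtype=float) * np.exp(eta)
    if not np.all(np.isfinite(mu)) or mu.max() > 1e12:
        bad = features["cluster_id"].to_numpy()[np.argmax(mu)]
        raise OverflowError(f"mean overflow for cluster {bad}")
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam).astype(np.int64)


def sample_feature_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Fast covariate-level sampler for inference calibration experiments.

    Draws independent covariates on the observed study scales (and baseline
    populations with a heavy-tailed lognormal) without building grids; the
    response column is left at zero for :func:`simulate_followup` to fill.
    Geometry columns (S, density, L) are made consistent with the drawn
    log-area/log-density values.
    """
    log_area = rng.normal(3.26, 1.07, n)
    log_density = rng.normal(3.53, 0.98, n)
    s = np.maximum(10, np.round(np.exp(log_area))).astype(int)
    density = np.exp(log_density)
    n_baseline = np.maximum(s, np.round(s * density)).astype(np.int64)
    f = pd.DataFrame({
        "cluster_id": np.arange(1, n + 1),
        "n_baseline": n_baseline,
        "n_followup": np.zeros(n, dtype=np.int64),
        "S": s,
        "density": n_baseline / s,
        "L": 2 * s + 2,
        "roundness": np.clip(rng.normal(0.434, 0.200, n), 0.05, 1.27),
        "irregularity": np.clip(rng.normal(2.327, 0.181, n), 1.7, 2.7),
        "cl": np.clip(rng.normal(0.301, 0.078, n), 0.1, 0.75),
        "heterogeneity": np.clip(rng.normal(1.119, 0.387, n), 0.0, 3.2),
        "gender": np.clip(rng.normal(0.520, 0.027, n), 0.0, 1.0),
        "age": rng.normal(44.6, 1.24, n),
        "tertiary": np.clip(rng.normal(0.653, 0.045, n), 0.0, 1.0),
    })
    return f


# ---------------------------------------------------------------------------
# full data sets

def _place_shapes(shapes, buffer: int):
    """Shelf-pack shapes left to right with `buffer` empty cells between
    bounding boxes; returns per-shape (col, row) offsets and canvas size."""
    boxes = []
    for shape in shapes:
        cols = [c for c, _ in shape]
        rows = [r for _, r in shape]
        boxes.append((min(cols), min(rows), max(cols) - min(cols) + 1,
                      max(rows) - min(rows) + 1))
    total_area = sum((w + buffer) * (h + buffer) for _, _, w, h in boxes)
    target_width = max(int(math.sqrt(total_area)) + 1,
                       max(w for _, _, w, _ in boxes) + buffer)
    offsets = []
    x = y = shelf = 0
    for (c0, r0, w, h) in boxes:
        if x + w > target_width and x > 0:
            x = 0
            y += shelf + buffer
            shelf = 0
        offsets.append((x - c0, y - r0))
        x += w + buffer
        shelf = max(shelf, h)
    return offsets, target_width, y + shelf


def generate_dataset(config: SyntheticConfig) -> tuple[PopulationGrid, RegionAttributeTable, SyntheticTruth]:
    """Generate a two-year grid, a covering region table, and the truth.

    Clusters are separated by at least `config.buffer` empty cells, so the
    clustering stage recovers exactly ``n_clusters`` components.  The stored
    truth features are the features the pipeline itself computes from the
    emitted grid (the loop is closed by construction); follow-up counts per
    cluster are NB2 draws given those features, scattered uniformly over the
    cluster's cells.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_clusters

    # heavy-tailed areas (truncated Pareto) and lognormal densities
    u = rng.random(n)
    areas = np.minimum(
        np.floor(config.area_min * (1.0 - u) ** (-1.0 / config.area_exponent)),
        config.area_max).astype(int)
    densities = np.exp(rng.normal(config.density_log_mean, config.density_log_sd, n))
    totals = np.maximum(areas, np.round(areas * densities)).astype(np.int64)
    elong = rng.uniform(0.0, config.elongation, n)

    shapes = [generate_shape(int(a), float(e), rng) for a, e in zip(areas, elong)]
    offsets, width, height = _place_shapes(shapes, config.buffer)

    coords_l, fem_l, male_l = [], [], []
    for shape, (dx, dy), total in zip(shapes, offsets, totals):
        coords, fem, male = _allocate_arrays(
            shape, int(total), config.concentration, config.heterogeneity_knob,
            config.gender_mean, rng)
        coords_l.append(coords + np.array([dx, dy], dtype=np.int64))
        fem_l.append(fem)
        male_l.append(male)
    bcoords = np.concatenate(coords_l)
    baseline = pd.DataFrame({
        "col": bcoords[:, 0], "row": bcoords[:, 1],
        "year": np.int64(config.baseline_year),
        "female": np.concatenate(fem_l), "male": np.concatenate(male_l),
    })

    # vertical region bands covering the whole canvas
    edges = np.linspace(0, width, config.n_regions + 1).astype(int)
    pad = 2 * config.buffer
    regions = pd.DataFrame({
        "region_id": [f"R{i:03d}" for i in range(config.n_regions)],
        "mean_age": rng.normal(config.age_mean, config.age_sd, config.n_regions),
        "tertiary_fraction": np.clip(
            rng.normal(config.tertiary_mean, config.tertiary_sd, config.n_regions),
            0.0, 1.0),
        "col_min": edges[:-1],
        "col_max": edges[1:] - 1,
        "row_min": -pad,
        "row_max": height + pad,
    })
    # make bands contiguous and extend the outermost ones past the canvas
    regions.loc[0, "col_min"] = -pad
    regions.loc[config.n_regions - 1, "col_max"] = width + pad
    for i in range(1, config.n_regions):
        regions.loc[i, "col_min"] = regions.loc[i - 1, "col_max"] + 1
    region_table = RegionAttributeTable(regions)

    years = (config.baseline_year, config.followup_year)
    grid0 = PopulationGrid(baseline, years=years, validate=False)
    clusters = find_clusters(grid0, config.baseline_year)
    if len(clusters) != n:
        raise RuntimeError(
            f"expected {n} clusters but found {len(clusters)}; "
            "increase the placement buffer or canvas")
    clusters = filter_min_area(clusters, min_cells=1)
    features = morphology.build_feature_table(clusters, grid0, region_table)

    ntilde = simulate_followup(features, config.beta, config.theta, rng)
    features = features.copy()
    features["n_followup"] = ntilde

    fcoords_l, ffem_l, fmale_l = [], [], []
    cell_lists = {cl.cluster_id: sorted(cl.cells, key=lambda cr: (cr[1], cr[0]))
                  for cl in clusters}
    for cid, nf in zip(features["cluster_id"], ntilde):
        if nf == 0:
            continue
        cells = cell_lists[cid]
        counts = rng.multinomial(int(nf), np.full(len(cells), 1.0 / len(cells)))
        keep = counts > 0
        coords = np.asarray(cells, dtype=np.int64)[keep]
        counts = counts[keep]
        female = rng.binomial(counts, config.gender_mean)
        fcoords_l.append(coords)
        ffem_l.append(female)
        fmale_l.append(counts - female)
    if fcoords_l:
        fc = np.concatenate(fcoords_l)
        follow = pd.DataFrame({
            "col": fc[:, 0], "row": fc[:, 1],
            "year": np.int64(config.followup_year),
            "female": np.concatenate(ffem_l), "male": np.concatenate(fmale_l),
        })
        all_rows = pd.concat([baseline, follow], ignore_index=True)
    else:
        all_rows = baseline
    grid = PopulationGrid(all_rows, years=years, validate=False)
    truth = SyntheticTruth(beta=dict(config.beta), theta=config.theta,
                           seed=config.seed, features=features, config=config)
    return grid, region_table, truth
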