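"""Gridded population I/O and region-attribute tables.

Conventions used throughout the package:

* A grid cell is addressed by integer indices ``(col, row)`` (east-positive,
  north-positive).  The cell *center* sits at exactly ``(col, row)`` and the
  cell side is one distance unit, so the cell footprint spans
  ``[col - 0.5, col + 0.5] x [row - 0.5, row + 0.5]``.  The physical side
  length (500 m for census mesh data) is metadata only: every downstream
  shape index is a ratio and does not depend on it.
* A cell is *populated* in year ``t`` iff its female + male count is >= 1.
* Water or otherwise empty cells are simply absent rows.

Grid CSV dialect: header ``col,row,year,female,male[,region_id]``, one row
per cell-year, UTF-8, comma separated.

Region CSV dialect: ``region_id,mean_age,tertiary_fraction,col_min,col_max,
row_min,row_max`` with inclusive integer cell bounds.  Region footprints are
rectangles of cells; point-in-region tests therefore use the continuous cell
footprint (bounds extended by half a cell side), so that a fractional
coordinate — e.g. the averaged position of tied central cells — still lands
in a region.  A point on a shared edge is assigned to the region with the
lexicographically smallest ``region_id``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

GRID_COLUMNS = ("col", "row", "year", "female", "male")
REGION_COLUMNS = (
    "region_id",
    "mean_age",
    "tertiary_fraction",
    "col_min",
    "col_max",
    "row_min",
    "row_max",
)


class GridValidationError(ValueError):
    """Raised when a grid or region table violates its contract."""


class RegionLookupError(KeyError):
    """Raised when a coordinate falls outside every region footprint."""


@dataclasses.dataclass(frozen=True)
class GridCell:
    """One raster cell with per-year female/male counts."""

    col: int
    row: int
    pop: dict  # year -> {"female": int, "male": int}
    region_id: str | None = None

    def total(self, year) -> int:
        counts = self.pop.get(year)
        if counts is None:
            return 0
        return int(counts["female"]) + int(counts["male"])

    def populated(self, year) -> bool:
        return self.total(year) >= 1


class PopulationGrid:
    """A gridded population data set at (usually) two time points.

    Parameters
    ----------
    data
        DataFrame with columns ``col,row,year,female,male`` and optionally
        ``region_id``; one row per cell-year.
    years
        Ordered pair ``(baseline, followup)``.  Defaults to the sorted
        distinct years present in ``data``.
    cell_side_physical
        Physical side length of a cell in metres (metadata only).
    """

    def __init__(self, data: pd.DataFrame, years: tuple | None = None,
                 cell_side_physical: float | None = None, validate: bool = True):
        df = pd.DataFrame(data).copy()
        missing = [c for c in GRID_COLUMNS if c not in df.columns]
        if missing:
            raise GridValidationError(f"grid data missing columns: {missing}")
        for c in ("col", "row", "year", "female", "male"):
            values = df[c].to_numpy()
            if validate and len(df):
                if not np.issubdtype(np.asarray(values).dtype, np.number):
                    raise GridValidationError(f"column {c!r} must be numeric")
                if not np.all(np.equal(np.mod(values, 1), 0)):
                    raise GridValidationError(f"column {c!r} must be integer-valued")
            df[c] = df[c].astype(np.int64)
        if validate:
            for c in ("female", "male"):
                bad = df.index[df[c] < 0]
                if len(bad):
                    raise GridValidationError(
                        f"negative {c} count at data row {bad[0]} "
                        f"(col={df.loc[bad[0], 'col']}, row={df.loc[bad[0], 'row']}, "
                        f"year={df.loc[bad[0], 'year']})")
            dup = df.duplicated(subset=["col", "row", "year"])
            if dup.any():
                first = df.index[dup][0]
                raise GridValidationError(
                    f"duplicate (col,row,year) entry at data row {first}: "
                    f"({df.loc[first, 'col']}, {df.loc[first, 'row']}, "
                    f"{df.loc[first, 'year']})")
        df = df.sort_values(["year", "row", "col"], kind="mergesort").reset_index(drop=True)
        self.data = df
        if years is None:
            years = tuple(sorted(df["year"].unique()))
        self.years = tuple(years)
        self.cell_side_physical = cell_side_physical
        self._maps: dict = {}

    # -- basic queries ---------------------------------------------------

    @property
    def baseline_year(self):
        return self.years[0]

    @property
    def followup_year(self):
        return self.years[-1]

    def total_population(self, year) -> int:
        sub = self.data[self.data["year"] == year]
        return int(sub["female"].sum() + sub["male"].sum())

    def population_map(self, year) -> dict:
        """Mapping ``(col, row) -> (female, male)`` for cells present at `year`."""
        if year not in self._maps:
            sub = self.data[self.data["year"] == year]
            self._maps[year] = {
                (int(c), int(r)): (int(f), int(m))
                for c, r, f, m in zip(sub["col"], sub["row"], sub["female"], sub["male"])
            }
        return self._maps[year]

    def populated_coords(self, year) -> list[tuple[int, int]]:
        """Coordinates of cells with >= 1 inhabitant at `year`, scan order."""
        return [coord for coord, (f, m) in sorted(self.population_map(year).items(),
                                                  key=lambda kv: (kv[0][1], kv[0][0]))
                if f + m >= 1]

    def cells(self) -> Iterator[GridCell]:
        by_cell: dict = {}
        region: dict = {}
        has_region = "region_id" in self.data.columns
        for tup in self.data.itertuples(index=False):
            key = (int(tup.col), int(tup.row))
            by_cell.setdefault(key, {})[tup.year] = {
                "female": int(tup.female), "male": int(tup.male)}
            if has_region:
                region[key] = tup.region_id
        for (c, r), pop in sorted(by_cell.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            yield GridCell(c, r, pop, region.get((c, r)))

    def __eq__(self, other):
        if not isinstance(other, PopulationGrid):
            return NotImplemented
        cols = [c for c in self.data.columns if c in other.data.columns]
        return (self.years == other.years
                and list(self.data.columns) == list(other.data.columns)
                and self.data[cols].equals(other.data[cols]))


def read_grid_csv(path, years: tuple | None = None,
                  cell_side_physical: float | None = None) -> PopulationGrid:
    """Read a grid CSV (``col,row,year,female,male[,region_id]``).

    Duplicate ``(col,row,year)`` rows and negative counts raise
    :class:`GridValidationError`; a cell with no row for a year is simply
    unpopulated that year.
    """
    df = pd.read_csv(path)
    return PopulationGrid(df, years=years, cell_side_physical=cell_side_physical)


def write_grid_csv(grid: PopulationGrid, path) -> None:
    """Write a grid CSV with deterministic row order (year, row, col)."""
    df = grid.data.sort_values(["year", "row", "col"], kind="mergesort")
    df.to_csv(path, index=False, lineterminator="\n")


class RegionAttributeTable:
    """Region attributes (mean age, tertiary-industry worker fraction) plus a
    rectangular coordinate -> region lookup.

    Substitutes a local lookup for the reverse-geocoding step used with real
    census data: the contract is identical (coordinate in, region out).
    """

    def __init__(self, df: pd.DataFrame):
        df = pd.DataFrame(df).copy()
        missing = [c for c in REGION_COLUMNS if c not in df.columns]
        if missing:
            raise GridValidationError(f"region table missing columns: {missing}")
        df["region_id"] = df["region_id"].astype(str)
        if df["region_id"].duplicated().any():
            raise GridValidationError("region_id values must be unique")
        bad = df[(df["tertiary_fraction"] < 0) | (df["tertiary_fraction"] > 1)]
        if len(bad):
            raise GridValidationError(
                f"tertiary_fraction outside [0, 1] for region "
                f"{bad['region_id'].iloc[0]!r}")
        for lo, hi in (("col_min", "col_max"), ("row_min", "row_max")):
            if (df[lo] > df[hi]).any():
                raise GridValidationError(f"{lo} > {hi} in region table")
        rows = df.to_dict("records")
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                if (a["col_min"] <= b["col_max"] and b["col_min"] <= a["col_max"]
                        and a["row_min"] <= b["row_max"] and b["row_min"] <= a["row_max"]):
                    raise GridValidationError(
                        f"region footprints overlap: {a['region_id']!r} and "
                        f"{b['region_id']!r}")
        self.df = df.sort_values("region_id", kind="mergesort").reset_index(drop=True)
        # flat arrays for fast point-in-rectangle lookups
        self._ids = self.df["region_id"].to_numpy()
        self._cmin = self.df["col_min"].to_numpy(dtype=float) - 0.5
        self._cmax = self.df["col_max"].to_numpy(dtype=float) + 0.5
        self._rmin = self.df["row_min"].to_numpy(dtype=float) - 0.5
        self._rmax = self.df["row_max"].to_numpy(dtype=float) + 0.5
        self._attrs = {
            str(r.region_id): (float(r.mean_age), float(r.tertiary_fraction))
            for r in self.df.itertuples(index=False)
        }

    def lookup(self, col: float, row: float) -> str:
        """Region containing the (possibly fractional) coordinate.

        Containment is on the continuous cell footprint (inclusive bounds
        extended by 0.5); ties on shared edges go to the lexicographically
        smallest ``region_id``.
        """
        hit = np.flatnonzero((self._cmin <= col) & (col <= self._cmax)
                             & (self._rmin <= row) & (row <= self._rmax))
        if hit.size == 0:
            raise RegionLookupError(
                f"coordinate ({col}, {row}) lies outside every region; "
                "extend the region table to cover it")
        return str(self._ids[hit[0]])  # ids sorted, so first hit is smallest

    def attributes(self, region_id: str) -> tuple[float, float]:
        try:
            return self._attrs[str(region_id)]
        except KeyError:
            raise RegionLookupError(f"unknown region_id {region_id!r}") from None

    def lookup_attributes(self, col: float, row: float) -> tuple[float, float]:
        return self.attributes(self.lookup(col, row))


def read_region_table(path) -> RegionAttributeTable:
    # round_trip parsing: region attributes must survive write/read exactly
    return RegionAttributeTable(pd.read_csv(path, float_precision="round_trip"))


def write_region_table(table: RegionAttributeTable, path) -> None:
    table.df.to_csv(path, index=False, lineterminator="\n")
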