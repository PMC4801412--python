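"""Analysis grid, per-cell fields and the presence/absence matrix.

The spatial frame for every downstream computation is a rectangular
latitude/longitude lattice with a boolean land mask.  Conventions, fixed
once here and relied on everywhere else:

* cells are half-open boxes ``[lon, lon + cell_size) x (lat - cell_size, lat]``;
* row 0 is the northernmost row;
* cell ``(r, c)`` has its center at
  ``(lat_max - (r + 0.5) * cell_size, lon_min + (c + 0.5) * cell_size)``;
* land cells are indexed row-major (scan rows north to south, columns
  west to east, keeping only land).

Missing values in a :class:`CellField` are carried in an explicit mask and
are never encoded as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, InvalidSpecError

__all__ = [
    "Grid",
    "CellField",
    "SpeciesRange",
    "PAMatrix",
    "build_grid",
    "richness",
    "restricted_range_subset",
    "clade_subset",
]


@dataclass(frozen=True)
class Grid:
    """Rectangular lat/lon lattice with a land mask.

    Parameters
    ----------
    lat_max
        Latitude of the northern edge of row 0, in degrees.
    lon_min
        Longitude of the western edge of column 0, in degrees.
    n_rows, n_cols
        Lattice dimensions.
    cell_size
        Cell edge length in degrees.
    land_mask
        Boolean ``(n_rows, n_cols)`` array; True marks land (analysis) cells.
    """

    lat_max: float
    lon_min: float
    n_rows: int
    n_cols: int
    cell_size: float
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.land_mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise InvalidSpecError(
                f"land_mask shape {mask.shape} does not match "
                f"({self.n_rows}, {self.n_cols})"
            )
        object.__setattr__(self, "land_mask", mask)

    # -- derived, cached lazily -------------------------------------------------
    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    @property
    def land_rc(self) -> np.ndarray:
        """(n_land, 2) array of (row, col) for land cells, row-major order."""
        return np.argwhere(self.land_mask)

    @property
    def land_index(self) -> np.ndarray:
        """(n_rows, n_cols) int array mapping cell -> land index, -1 off land."""
        idx = np.full((self.n_rows, self.n_cols), -1, dtype=np.int64)
        idx[self.land_mask] = np.arange(self.n_land)
        return idx

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        """(lat, lon) of the center of cell (r, c)."""
        return (
            self.lat_max - (r + 0.5) * self.cell_size,
            self.lon_min + (c + 0.5) * self.cell_size,
        )

    def land_centers(self) -> np.ndarray:
        """(n_land, 2) array of (lat, lon) centers of land cells."""
        rc = self.land_rc
        lat = self.lat_max - (rc[:, 0] + 0.5) * self.cell_size
        lon = self.lon_min + (rc[:, 1] + 0.5) * self.cell_size
        return np.column_stack([lat, lon])

    def cell_bounds(self, r: int, c: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of cell (r, c)."""
        lon0 = self.lon_min + c * self.cell_size
        lat1 = self.lat_max - r * self.cell_size
        return (lon0, lat1 - self.cell_size, lon0 + self.cell_size, lat1)

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.lat_max - other.lat_max) <= tol
            and abs(self.lon_min - other.lon_min) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
            and bool(np.array_equal(self.land_mask, other.land_mask))
        )

    def require_same_geometry(self, other: "Grid") -> None:
        if not self.same_geometry(other):
            raise GridMismatchError(
                f"grid geometries differ: "
                f"({self.lat_max}, {self.lon_min}, {self.n_rows}x{self.n_cols}, "
                f"{self.cell_size}) vs ({other.lat_max}, {other.lon_min}, "
                f"{other.n_rows}x{other.n_cols}, {other.cell_size})"
            )


def build_grid(
    lat_max: float,
    lon_min: float,
    n_rows: int,
    n_cols: int,
    cell_size: float,
    land_mask: np.ndarray | None = None,
) -> Grid:
    """Construct a :class:`Grid`; an omitted mask means all cells are land."""
    if n_rows < 1 or n_cols < 1:
        raise InvalidSpecError("n_rows and n_cols must be >= 1")
    if cell_size <= 0:
        raise InvalidSpecError("cell_size must be positive")
    if land_mask is None:
        land_mask = np.ones((n_rows, n_cols), dtype=bool)
    return Grid(lat_max, lon_min, n_rows, n_cols, cell_size, land_mask)


@dataclass
class CellField:
    """One real value per land cell with an explicit missing mask."""

    grid: Grid
    values: np.ndarray
    missing: np.ndarray | None = None
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_land,):
            raise GridMismatchError(
                f"field '{self.name}' has {self.values.shape[0] if self.values.ndim else 0} "
                f"values for {self.grid.n_land} land cells"
            )
        if self.missing is None:
            self.missing = np.zeros(self.grid.n_land, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (self.grid.n_land,):
                raise GridMismatchError("missing mask length does not match land cells")

    @property
    def defined(self) -> np.ndarray:
        return ~self.missing

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]

    def to_array(self) -> np.ndarray:
        """Full (n_rows, n_cols) array; off-land and missing cells are NaN."""
        out = np.full((self.grid.n_rows, self.grid.n_cols), np.nan)
        rc = self.grid.land_rc
        vals = np.where(self.missing, np.nan, self.values)
        out[rc[:, 0], rc[:, 1]] = vals
        return out

    def with_values(self, values: np.ndarray, name: str | None = None) -> "CellField":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            name=self.name if name is None else name,
        )


@dataclass(frozen=True)
class SpeciesRange:
    """A species' geographic range: a polygon in lon/lat degrees or an
    explicit cell set.

    ``clade_path`` is an ordered tuple of labels from coarse to fine
    (e.g. ``("Caviomorpha", "Octodontoidea", "Ctenomyini")``).
    """

    species_id: str
    clade_path: tuple[str, ...] = ()
    geometry: object | None = None  # shapely (Multi)Polygon
    cells: frozenset[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.geometry is None and self.cells is None:
            raise InvalidSpecError(
                f"species '{self.species_id}' has neither geometry nor cell set"
            )
        if self.cells is not None:
            object.__setattr__(self, "cells", frozenset(self.cells))


@dataclass
class PAMatrix:
    """Cells-by-species boolean incidence matrix with species metadata.

    ``incidence`` has one row per land cell (grid row-major order) and one
    column per species.  ``species_meta`` is indexed by species id and
    carries ``clade_path`` (slash-joined string) and ``range_size_cells``
    (always equal to the species' column sum).
    """

    grid: Grid
    species_ids: list[str]
    incidence: np.ndarray
    species_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    empty_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (self.grid.n_land, len(self.species_ids)):
            raise GridMismatchError(
                f"incidence shape {self.incidence.shape} does not match "
                f"({self.grid.n_land} land cells, {len(self.species_ids)} species)"
            )
        if len(set(self.species_ids)) != len(self.species_ids):
            raise InvalidSpecError("duplicate species_id in PAMatrix")
        sizes = self.incidence.sum(axis=0).astype(int)
        if self.species_meta is None:
            self.species_meta = pd.DataFrame(
                {"clade_path": [""] * len(self.species_ids), "range_size_cells": sizes},
                index=pd.Index(self.species_ids, name="species_id"),
            )
        else:
            self.species_meta = self.species_meta.loc[self.species_ids].copy()
            self.species_meta["range_size_cells"] = sizes

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def subset(self, species: Sequence[str]) -> "PAMatrix":
        pos = {s: i for i, s in enumerate(self.species_ids)}
        cols = [pos[s] for s in species]
        return PAMatrix(
            grid=self.grid,
            species_ids=list(species),
            incidence=self.incidence[:, cols],
            species_meta=self.species_meta.loc[list(species)],
        )


def richness(pam: PAMatrix) -> CellField:
    """Species richness per cell: the number of species present."""
    counts = pam.incidence.sum(axis=1).astype(float)
    return CellField(grid=pam.grid, values=counts, name="richness", units="species")


def restricted_range_subset(pam: PAMatrix, quantile: float = 0.25) -> PAMatrix:
    """Sub-matrix of the ``ceil(quantile * S)`` species with the smallest
    ranges (range size measured in occupied cells).

    Ties at the cutoff are broken deterministically by species id, so the
    subset size is exactly ``ceil(quantile * S)``.
    """
    if not (0 < quantile < 1):
        raise InvalidSpecError("quantile must lie strictly between 0 and 1")
    sizes = pam.species_meta["range_size_cells"]
    order = sorted(pam.species_ids, key=lambda s: (int(sizes[s]), s))
    k = int(np.ceil(quantile * pam.n_species))
    return pam.subset(order[:k])


def clade_subset(pam: PAMatrix, clade_label: str) -> PAMatrix:
    """Species whose clade path contains ``clade_label``."""
    paths = pam.species_meta["clade_path"]
    keep = [s for s in pam.species_ids if clade_label in str(paths[s]).split("/")]
    if not keep:
        known = sorted({p for s in pam.species_ids for p in str(paths[s]).split("/") if p})
        from .exceptions import UnknownCladeError

        raise UnknownCladeError(
            f"clade label {clade_label!r} matches no species; known labels: {known}"
        )
    return pam.subset(keep)
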