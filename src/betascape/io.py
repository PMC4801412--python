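"""Readers and writers for the package's plain-text formats.

* grid definition — JSON (`lat_max`, `lon_min`, `n_rows`, `n_cols`,
  `cell_size`, run-length-free `land_mask` as nested 0/1 lists);
* gridded field — CSV with columns ``row,col,value`` (plus
  ``neighbor_count`` for neighborhood fields); one line per land cell,
  empty value = missing; reals carry 17 significant digits so round trips
  are loss-free;
* presence/absence matrix — CSV, first two columns ``row,col`` then one
  0/1 column per species, plus a JSON sidecar (``<file>.meta.json``) with
  clade paths;
* species ranges — GeoJSON FeatureCollection (properties ``species``,
  ``clade_path`` as ``"A/B/C"``) or per-species cell-list CSV
  (``species_id,row,col``).

Readers validate grid congruence (origin, cell size, dimensions within
1e-9 degrees) instead of trusting the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .beta import NeighborhoodField
from .exceptions import ConfigError, GridMismatchError, InvalidSpecError
from .grid import CellField, Grid, PAMatrix, SpeciesRange, build_grid

__all__ = [
    "write_grid",
    "read_grid",
    "write_field",
    "read_field",
    "write_pam",
    "read_pam",
    "read_ranges_geojson",
    "write_ranges_geojson",
    "read_ranges_cells_csv",
    "write_ranges_cells_csv",
]

_FMT = "%.17g"


def write_grid(grid: Grid, path: str | Path) -> None:
    doc = {
        "lat_max": grid.lat_max,
        "lon_min": grid.lon_min,
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "cell_size": grid.cell_size,
        "land_mask": grid.land_mask.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_grid(path: str | Path) -> Grid:
    doc = json.loads(Path(path).read_text())
    try:
        return build_grid(
            doc["lat_max"],
            doc["lon_min"],
            int(doc["n_rows"]),
            int(doc["n_cols"]),
            doc["cell_size"],
            np.asarray(doc["land_mask"], dtype=bool),
        )
    except KeyError as e:
        raise ConfigError(f"grid file {path} is missing key {e}") from e


def write_field(field: CellField, path: str | Path) -> None:
    rc = field.grid.land_rc
    is_nbh = isinstance(field, NeighborhoodField)
    with open(path, "w") as fh:
        header = "row,col,value" + (",neighbor_count" if is_nbh else "")
        fh.write(header + "\n")
        for i, (r, c) in enumerate(rc):
            val = "" if field.missing[i] else _FMT % field.values[i]
            line = f"{r},{c},{val}"
            if is_nbh:
                line += f",{field.neighbor_count[i]}"
            fh.write(line + "\n")


def read_field(path: str | Path, grid: Grid, name: str = "", units: str = "") -> CellField:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"row", "col", "value"}.issubset(df.columns):
        raise ConfigError(f"field file {path} lacks row,col,value columns")
    idx = grid.land_index
    if len(df) != grid.n_land:
        raise GridMismatchError(
            f"field file {path} lists {len(df)} cells; grid has {grid.n_land} land cells"
        )
    values = np.full(grid.n_land, np.nan)
    missing = np.ones(grid.n_land, dtype=bool)
    for _, rec in df.iterrows():
        r, c = int(rec["row"]), int(rec["col"])
        if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols) or idx[r, c] < 0:
            raise GridMismatchError(f"cell ({r},{c}) in {path} is not a land cell of the grid")
        i = idx[r, c]
        v = rec["value"]
        if pd.notna(v):
            values[i] = float(v)
            missing[i] = False
    if "neighbor_count" in df.columns:
        counts = np.zeros(grid.n_land, dtype=int)
        for _, rec in df.iterrows():
            counts[idx[int(rec["row"]), int(rec["col"])]] = int(rec["neighbor_count"])
        return NeighborhoodField(
            grid=grid, values=values, missing=missing, name=name, units=units, neighbor_count=counts
        )
    return CellField(grid=grid, values=values, missing=missing, name=name, units=units)


def write_pam(pam: PAMatrix, path: str | Path) -> None:
    path = Path(path)
    rc = pam.grid.land_rc
    df = pd.DataFrame(pam.incidence.astype(int), columns=pam.species_ids)
    df.insert(0, "col", rc[:, 1])
    df.insert(0, "row", rc[:, 0])
    df.to_csv(path, index=False)
    meta = {
        "clade_path": {s: str(pam.species_meta.loc[s, "clade_path"]) for s in pam.species_ids},
        "empty_species": pam.empty_species,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_pam(path: str | Path, grid: Grid) -> PAMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    # incidence entries are integral; no float parsing concerns here
    if list(df.columns[:2]) != ["row", "col"]:
        raise ConfigError(f"PAM file {path} must start with row,col columns")
    species = list(df.columns[2:])
    if not species:
        raise ConfigError(f"PAM file {path} has no species columns")
    idx = grid.land_index
    rows = df["row"].to_numpy(int)
    cols = df["col"].to_numpy(int)
    land = idx[rows, cols]
    if (land < 0).any():
        bad = np.argmax(land < 0)
        raise GridMismatchError(
            f"cell ({rows[bad]},{cols[bad]}) in {path} is not a land cell"
        )
    if len(df) != grid.n_land or len(set(map(tuple, np.column_stack([rows, cols])))) != grid.n_land:
        raise GridMismatchError(
            f"PAM file {path} has {len(df)} cells; grid has {grid.n_land} land cells"
        )
    raw = df[species].to_numpy()
    if not np.isin(raw, (0, 1)).all():
        bad = np.argwhere(~np.isin(raw, (0, 1)))[0]
        raise ConfigError(
            f"PAM file {path}: non-boolean entry at data row {bad[0]}, "
            f"species {species[bad[1]]!r}"
        )
    incidence = np.zeros((grid.n_land, len(species)), dtype=bool)
    incidence[land] = raw.astype(bool)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_df = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        meta_df = pd.DataFrame(
            {"clade_path": [meta["clade_path"].get(s, "") for s in species]},
            index=pd.Index(species, name="species_id"),
        )
        meta_df["range_size_cells"] = incidence.sum(axis=0)
    return PAMatrix(grid=grid, species_ids=species, incidence=incidence, species_meta=meta_df)


# ---------------------------------------------------------------------------
# species ranges


def read_ranges_geojson(path: str | Path) -> list[SpeciesRange]:
    from shapely.geometry import shape

    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ConfigError(f"{path} is not a GeoJSON FeatureCollection")
    out = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        sid = props.get("species")
        if sid is None:
            raise ConfigError(f"{path}: feature without a 'species' property")
        clade = tuple(p for p in str(props.get("clade_path", "")).split("/") if p)
        out.append(
            SpeciesRange(species_id=str(sid), clade_path=clade, geometry=shape(feat["geometry"]))
        )
    if not out:
        raise ConfigError(f"{path} contains no features")
    return out


def write_ranges_geojson(ranges: list[SpeciesRange], grid: Grid, path: str | Path) -> None:
    """Write ranges as cell-union polygons (cell-set ranges are unioned)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    feats = []
    for rng in ranges:
        if rng.geometry is not None:
            geom = rng.geometry
        else:
            geom = unary_union([box(*grid.cell_bounds(r, c)) for (r, c) in sorted(rng.cells)])
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "species": rng.species_id,
                    "clade_path": "/".join(rng.clade_path),
                },
                "geometry": mapping(geom),
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def write_ranges_cells_csv(ranges: list[SpeciesRange], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id,row,col\n")
        for rng in ranges:
            if rng.cells is None:
                raise InvalidSpecError(
                    f"species '{rng.species_id}' has no explicit cell set; rasterize first"
                )
            for r, c in sorted(rng.cells):
                fh.write(f"{rng.species_id},{r},{c}\n")


def read_ranges_cells_csv(path: str | Path, clade_paths: dict[str, str] | None = None) -> list[SpeciesRange]:
    df = pd.read_csv(path)
    if not {"species_id", "row", "col"}.issubset(df.columns):
        raise ConfigError(f"{path} lacks species_id,row,col columns")
    out = []
    for sid, sub in df.groupby("species_id", sort=False):
        clade = tuple(
            p for p in str((clade_paths or {}).get(str(sid), "")).split("/") if p
        )
        cells = frozenset((int(r), int(c)) for r, c in zip(sub["row"], sub["col"]))
        out.append(SpeciesRange(species_id=str(sid), clade_path=clade, cells=cells))
    return out
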