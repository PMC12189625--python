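"""Gridded-layer and occurrence I/O.

Conventions
-----------
* Coordinates are WGS84 decimal degrees throughout; no projection is applied.
* Grids are cell-center registered. Row 0 is the southernmost row, column 0
  the westernmost column; latitude increases with row index.
* Cell membership is half-open: a cell covers ``[west, west + cs)`` x
  ``[south, south + cs)``; the outermost northern/eastern boundary is closed
  so that every point inside the grid bounding box maps to exactly one cell.
* Layers are written as plain CSV (one row per cell, ``lon,lat,<variables>``)
  so fixtures survive text-only storage; masks travel implicitly as the set
  of rows present.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError, GridError

logger = logging.getLogger(__name__)

#: Canonical environmental variable names, in canonical column order.
VARIABLES = (
    "temperature_mean",
    "temperature_ltmin",
    "temperature_ltmax",
    "salinity_mean",
    "salinity_ltmin",
    "salinity_ltmax",
    "velocity_mean",
    "productivity_mean",
    "nitrate_mean",
)

#: Variables expressed in degrees Celsius (additive scenario offsets apply).
TEMPERATURE_VARIABLES = (
    "temperature_mean",
    "temperature_ltmin",
    "temperature_ltmax",
)

PAST_PRESENT_CUTOFF_YEAR = 2000


@dataclass(frozen=True)
class GridSpec:
    """Cell-center registered regular lon/lat grid.

    ``origin_lon``/``origin_lat`` are the center of cell ``(0, 0)`` (the
    south-west corner cell).
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError(
                f"grid extent must be positive, got {self.n_rows}x{self.n_cols}"
            )

    # -- geometry -----------------------------------------------------------
    @property
    def west(self) -> float:
        return self.origin_lon - self.cell_size / 2

    @property
    def south(self) -> float:
        return self.origin_lat - self.cell_size / 2

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    @property
    def north(self) -> float:
        return self.south + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lons(self) -> np.ndarray:
        """Cell-center longitudes, one per column."""
        return self.origin_lon + self.cell_size * np.arange(self.n_cols)

    def lats(self) -> np.ndarray:
        """Cell-center latitudes, one per row (south to north)."""
        return self.origin_lat + self.cell_size * np.arange(self.n_rows)

    def lon_lat_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.lons(), self.lats())

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.west)
            & (lon <= self.east)
            & (lat >= self.south)
            & (lat <= self.north)
        )

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map points to (row, col).

        Half-open membership; points exactly on the closed north/east outer
        boundary fold into the outermost cell. Out-of-bounds points raise.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if not np.all(self.contains(lon, lat)):
            raise DataError("point outside grid bounding box")
        # snap tolerance absorbs float error at exact cell boundaries
        eps = 1e-9
        col = np.floor((lon - self.west) / self.cell_size + eps).astype(int)
        row = np.floor((lat - self.south) / self.cell_size + eps).astype(int)
        col = np.minimum(col, self.n_cols - 1)
        row = np.minimum(row, self.n_rows - 1)
        return row, col

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid of ``factor x factor`` blocks; requires exact divisibility."""
        if self.n_rows % factor or self.n_cols % factor:
            raise AlignmentError(
                f"{self.n_rows}x{self.n_cols} grid not divisible into "
                f"{factor}x{factor} blocks"
            )
        cs = self.cell_size * factor
        return GridSpec(
            origin_lon=self.west + cs / 2,
            origin_lat=self.south + cs / 2,
            cell_size=cs,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
        )

    def to_dict(self) -> dict:
        return {
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "cell_size": self.cell_size,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class EnvLayerStack:
    """Aligned environmental layers sharing one validity mask.

    ``layers`` maps variable name to a float array of ``grid.shape``;
    ``mask`` is boolean, True where cells are valid. Masked cells hold NaN.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise AlignmentError("mask shape does not match grid")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise AlignmentError(f"layer {name!r} shape does not match grid")
            if not np.all(np.isfinite(arr[self.mask])):
                raise DataError(f"layer {name!r} has non-finite unmasked values")
            arr = arr.copy()
            arr[~self.mask] = np.nan
            self.layers[name] = arr

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def values_at(self, rows, cols, variables=None) -> np.ndarray:
        variables = list(variables) if variables is not None else self.variable_names
        return np.column_stack([self.layers[v][rows, cols] for v in variables])

    def background_matrix(self, variables=None) -> np.ndarray:
        """Design matrix over all unmasked cells (row-major cell order)."""
        variables = list(variables) if variables is not None else self.variable_names
        return np.column_stack([self.layers[v][self.mask] for v in variables])

    def with_layers(self, layers: dict[str, np.ndarray]) -> "EnvLayerStack":
        return EnvLayerStack(grid=self.grid, layers=layers, mask=self.mask.copy())

    def copy(self) -> "EnvLayerStack":
        return EnvLayerStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            mask=self.mask.copy(),
        )


@dataclass
class OccurrenceSet:
    """Presence records for one species with past/present era labels."""

    species: str
    records: pd.DataFrame  # columns: lon, lat, year, era
    deduplicated: bool = False

    def __post_init__(self):
        required = {"lon", "lat", "year"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"occurrence frame missing columns: {sorted(missing)}")
        if "era" not in self.records.columns:
            self.records = self.records.assign(era=era_of(self.records["year"]))

    def __len__(self) -> int:
        return len(self.records)

    def subset_era(self, era: str) -> "OccurrenceSet":
        return OccurrenceSet(
            species=self.species,
            records=self.records[self.records["era"] == era].reset_index(drop=True),
            deduplicated=self.deduplicated,
        )


def era_of(year) -> np.ndarray:
    """'past' for years before 2000, 'present' from 2000 onwards."""
    year = np.asarray(year)
    return np.where(year < PAST_PRESENT_CUTOFF_YEAR, "past", "present")


# ---------------------------------------------------------------------------
# Occurrence I/O
# ---------------------------------------------------------------------------

def load_occurrences(path, grid: GridSpec, species: str | None = None) -> OccurrenceSet:
    """Read an occurrence CSV (``species,lon,lat,year``) clipped to *grid*.

    Records outside the grid bounding box are dropped (count logged). If the
    file holds several species, *species* selects one; otherwise the file
    must be single-species.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["species", "lon", "lat", "year"])
    missing = {"species", "lon", "lat", "year"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("lon", "lat", "year"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            line = int(df.index[bad][0]) + 2 if bad.any() else -1
            raise FormatError(f"{path}: unparseable {col!r} near line {line}") from exc
    df["year"] = df["year"].astype(int)

    if species is not None:
        df = df[df["species"] == species]
    else:
        names = df["species"].unique()
        if len(names) > 1:
            raise FormatError(f"{path}: multiple species present, pass species=")
        species = names[0] if len(names) else "unknown"

    inside = grid.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("%s: dropped %d records outside grid bounds", path, n_dropped)
    df = df[inside].reset_index(drop=True)
    return OccurrenceSet(
        species=str(species),
        records=df[["lon", "lat", "year"]].copy(),
    )


def write_occurrences(occ: OccurrenceSet, path) -> None:
    out = occ.records[["lon", "lat", "year"]].copy()
    out.insert(0, "species", occ.species)
    out.to_csv(path, index=False, float_format="%.8f")


def dedup_to_grid(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Collapse records to one per occupied grid cell per era.

    The representative is the first record in file order. Idempotent.
    """
    df = occ.records
    if df.empty:
        return replace(occ, deduplicated=True)
    row, col = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    key = pd.DataFrame({"row": row, "col": col, "era": df["era"]})
    keep = ~key.duplicated(keep="first")
    return OccurrenceSet(
        species=occ.species,
        records=df[keep].reset_index(drop=True),
        deduplicated=True,
    )


def extract_at_points(
    stack: EnvLayerStack,
    occ: OccurrenceSet,
    variables=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of layer values at occurrence points.

    Points falling on masked cells are dropped (count logged). Returns
    ``(matrix, kept)`` where *kept* is the boolean row filter applied to
    ``occ.records``. Column order follows *variables* (default: stack order).

    Raises :class:`DataError` if every point lands on a masked cell.
    """
    variables = list(variables) if variables is not None else stack.variable_names
    df = occ.records
    if df.empty:
        raise DataError("no occurrence records to extract")
    row, col = stack.grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    valid = stack.mask[row, col]
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d occurrence points on masked cells", occ.species, n_dropped
        )
    if not valid.any():
        raise DataError("all occurrence points fall on masked cells")
    matrix = stack.values_at(row[valid], col[valid], variables)
    return matrix, valid


# ---------------------------------------------------------------------------
# Raster I/O (CSV grid + JSON sidecar-free header comment)
# ---------------------------------------------------------------------------

def write_stack_csv(stack: EnvLayerStack, path) -> None:
    """Write a stack as long-format CSV: one row per valid cell.

    The grid definition is embedded as a ``# grid: {...}`` comment on the
    first line so a stack round-trips from a single text file.
    """
    lon_m, lat_m = stack.grid.lon_lat_mesh()
    m = stack.mask
    data = {"lon": lon_m[m], "lat": lat_m[m]}
    for name in stack.variable_names:
        data[name] = stack.layers[name][m]
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(f"# grid: {json.dumps(stack.grid.to_dict())}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_stack_csv(path) -> EnvLayerStack:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# grid:"):
            raise FormatError(f"{path}: missing '# grid:' header line")
        grid = GridSpec.from_dict(json.loads(header.split(":", 1)[1]))
        df = pd.read_csv(fh)
    row, col = grid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
    mask = np.zeros(grid.shape, dtype=bool)
    mask[row, col] = True
    layers = {}
    for name in df.columns:
        if name in ("lon", "lat"):
            continue
        arr = np.full(grid.shape, np.nan)
        arr[row, col] = df[name].to_numpy(dtype=float)
        layers[name] = arr
    return EnvLayerStack(grid=grid, layers=layers, mask=mask)


def write_field_csv(grid: GridSpec, field_arr: np.ndarray, name: str, path) -> None:
    """Write a single 2-D field (NaN = invalid) as long-format CSV."""
    valid = np.isfinite(np.asarray(field_arr, dtype=float))
    lon_m, lat_m = grid.lon_lat_mesh()
    df = pd.DataFrame(
        {"lon": lon_m[valid], "lat": lat_m[valid], name: field_arr[valid]}
    )
    with open(path, "w") as fh:
        fh.write(f"# grid: {json.dumps(grid.to_dict())}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# MPA masks (GeoJSON polygons <-> 0/1 raster by cell-center containment)
# ---------------------------------------------------------------------------

def rasterize_polygons(polygons, grid: GridSpec) -> np.ndarray:
    """0/1 raster: 1 where the cell center falls inside any polygon."""
    from shapely.geometry import Point
    from shapely.prepared import prep
    from shapely.ops import unary_union

    union = prep(unary_union(list(polygons)))
    out = np.zeros(grid.shape, dtype=np.uint8)
    lons, lats = grid.lons(), grid.lats()
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            if union.contains(Point(lo, la)):
                out[i, j] = 1
    return out


def read_mpa_geojson(path, grid: GridSpec) -> np.ndarray:
    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    polys = [shape(f["geometry"]) for f in feats]
    return rasterize_polygons(polys, grid)


def write_mpa_geojson(polygons, path) -> None:
    from shapely.geometry import mapping

    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(p)}
            for p in polygons
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
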