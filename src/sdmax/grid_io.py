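"""Raster and occurrence I/O.

Rasters are single-band ESRI ASCII grids in geographic WGS84 coordinates,
rows stored north-to-south. Cells are half-open on their east and north
edges, so a point exactly on the west/south edge of a cell belongs to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "EnvStack",
    "OccurrenceSet",
    "GridFormatError",
    "GridAlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_samples_csv",
    "write_samples_csv",
    "OUTSIDE",
]

DEFAULT_NODATA = -9999.0

#: Sentinel returned by :meth:`RasterGrid.cell_index` for out-of-extent points.
OUTSIDE = None


class GridFormatError(ValueError):
    """Malformed ASCII grid header or body."""


class GridAlignmentError(ValueError):
    """Grids expected to share a header do not."""


@dataclass
class RasterGrid:
    """One aligned single-band grid with georeferencing header and NODATA.

    ``values`` is an ``(nrows, ncols)`` float array in north-to-south row
    order; NODATA cells carry ``nodata_value``.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float
    values: np.ndarray
    variable_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ncols, self.nrows = int(self.ncols), int(self.nrows)
        self.nodata_value = float(self.nodata_value)
        self.cellsize = float(self.cellsize)
        if self.cellsize <= 0:
            raise GridFormatError(f"cellsize must be positive, got {self.cellsize}")
        if self.ncols <= 0 or self.nrows <= 0:
            raise GridFormatError("grid dimensions must be positive")
        if self.values.shape != (self.nrows, self.ncols):
            raise GridFormatError(
                f"values shape {self.values.shape} does not match header "
                f"({self.nrows}, {self.ncols})"
            )
        data = self.values[~self.nodata_mask()]
        if data.size and not np.all(np.isfinite(data)):
            raise GridFormatError("non-NODATA values must be finite")

    # -- masks ---------------------------------------------------------------

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask, True where the cell is NODATA."""
        with np.errstate(invalid="ignore"):
            return (self.values == self.nodata_value) | np.isnan(self.values)

    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask()

    # -- georeferencing ------------------------------------------------------

    def header(self) -> dict:
        return {
            "ncols": self.ncols,
            "nrows": self.nrows,
            "xllcorner": self.xllcorner,
            "yllcorner": self.yllcorner,
            "cellsize": self.cellsize,
            "nodata_value": self.nodata_value,
        }

    def same_header(self, other: "RasterGrid", rtol: float = 1e-9) -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and math.isclose(self.xllcorner, other.xllcorner, rel_tol=rtol, abs_tol=1e-12)
            and math.isclose(self.yllcorner, other.yllcorner, rel_tol=rtol, abs_tol=1e-12)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=rtol)
        )

    def cell_index(self, lon: float, lat: float):
        """Map a point to its (row, col) cell, or ``OUTSIDE``.

        Cells are half-open: ``[x_left, x_left + cellsize)`` by
        ``[y_bottom, y_bottom + cellsize)``.
        """
        col = math.floor((lon - self.xllcorner) / self.cellsize)
        row_from_bottom = math.floor((lat - self.yllcorner) / self.cellsize)
        if col < 0 or col >= self.ncols or row_from_bottom < 0 or row_from_bottom >= self.nrows:
            return OUTSIDE
        return self.nrows - 1 - row_from_bottom, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def cell_latitudes(self) -> np.ndarray:
        """Latitude of each row's cell centers (north-to-south)."""
        rows = np.arange(self.nrows)
        return self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize

    def with_values(self, values: np.ndarray, variable_name: str | None = None) -> "RasterGrid":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            variable_name=self.variable_name if variable_name is None else variable_name,
        )


@dataclass
class EnvStack:
    """Named, aligned set of raster layers under one scenario label."""

    layers: list[RasterGrid] = field(default_factory=list)
    scenario_label: str = "current"
    period_label: str = ""

    def __post_init__(self) -> None:
        names = [g.variable_name for g in self.layers]
        if len(set(names)) != len(names):
            raise GridAlignmentError(f"duplicate variable names in stack: {names}")
        if self.layers:
            ref = self.layers[0]
            for g in self.layers[1:]:
                if not g.same_header(ref):
                    raise GridAlignmentError(
                        f"layer {g.variable_name!r} misaligned with {ref.variable_name!r}"
                    )

    def __iter__(self) -> Iterator[RasterGrid]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def variables(self) -> list[str]:
        return [g.variable_name for g in self.layers]

    def __getitem__(self, name: str) -> RasterGrid:
        for g in self.layers:
            if g.variable_name == name:
                return g
        raise KeyError(f"variable {name!r} not in stack {self.variables}")

    def template(self) -> RasterGrid:
        if not self.layers:
            raise ValueError("empty stack has no template grid")
        return self.layers[0]

    def valid_mask(self) -> np.ndarray:
        """A cell is valid only if valid in every layer."""
        mask = self.layers[0].valid_mask()
        for g in self.layers[1:]:
            mask &= g.valid_mask()
        return mask

    def values_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) array of layer values at cell indices."""
        return np.column_stack([g.values[rows, cols] for g in self.layers])


@dataclass
class OccurrenceSet:
    """Presence point records in geographic WGS84."""

    records: list[tuple[str, float, float]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [""] * len(self.records)
        if len(self.provenance) != len(self.records):
            raise ValueError("provenance length must match records")
        for _, lon, lat in self.records:
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise ValueError(f"coordinate out of range: ({lon}, {lat})")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.array([r[2] for r in self.records], dtype=float)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path, variable_name: str = "", units: str = "") -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).

    Expects the standard 6-line header (case-insensitive keys, NODATA_value
    spelled in any case) followed by whitespace-separated rows, north first.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().split("\n")
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines[:6]):
        parts = line.split()
        if len(parts) != 2:
            raise GridFormatError(f"{path.name} line {i + 1}: expected 'key value', got {line!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise GridFormatError(f"{path.name} line {i + 1}: unknown header key {parts[0]!r}")
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise GridFormatError(f"{path.name} line {i + 1}: non-numeric value {parts[1]!r}") from exc
        body_start = i + 1
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"{path.name}: missing header keys {missing}")

    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    body = " ".join(lines[body_start:])
    tokens = body.split()
    try:
        flat = np.array(tokens, dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"{path.name}: non-numeric cell value in body") from exc
    if flat.size != nrows * ncols:
        raise GridFormatError(
            f"{path.name}: expected {nrows * ncols} values, found {flat.size}"
        )
    if not variable_name:
        variable_name = path.stem
    return RasterGrid(
        ncols=ncols,
        nrows=nrows,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata_value=header["nodata_value"],
        values=flat.reshape(nrows, ncols),
        variable_name=variable_name,
        units=units,
    )


def write_ascii_grid(grid: RasterGrid, path, precision: int = 10) -> None:
    """Write a grid as ESRI ASCII, re-readable to printed precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = f"%.{precision}g"
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {fmt % grid.xllcorner}\n")
        fh.write(f"yllcorner {fmt % grid.yllcorner}\n")
        fh.write(f"cellsize {fmt % grid.cellsize}\n")
        fh.write(f"NODATA_value {fmt % grid.nodata_value}\n")
        for row in grid.values:
            fh.write(" ".join(fmt % v for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Occurrence CSV (MaxEnt "samples" layout: species, longitude, latitude)
# ---------------------------------------------------------------------------


def read_samples_csv(path) -> tuple[OccurrenceSet, int]:
    """Read an occurrences CSV.

    Returns the occurrence set and the number of rows dropped because their
    coordinates were unparsable or out of range.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    lon_col = cols.get("longitude", cols.get("lon"))
    lat_col = cols.get("latitude", cols.get("lat"))
    if lon_col is None or lat_col is None:
        raise GridFormatError(f"{path}: missing longitude/latitude columns ({list(df.columns)})")
    sp_col = cols.get("species")
    records: list[tuple[str, float, float]] = []
    dropped = 0
    for _, row in df.iterrows():
        lon = pd.to_numeric(row[lon_col], errors="coerce")
        lat = pd.to_numeric(row[lat_col], errors="coerce")
        if pd.isna(lon) or pd.isna(lat) or not (-180 <= lon <= 180 and -90 <= lat <= 90):
            dropped += 1
            continue
        species = str(row[sp_col]) if sp_col is not None else "species"
        records.append((species, float(lon), float(lat)))
    return OccurrenceSet(records=records), dropped


def write_samples_csv(occ: OccurrenceSet, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(occ.records, columns=["species", "longitude", "latitude"])
    df.to_csv(path, index=False)
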