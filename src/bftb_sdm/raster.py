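"""Lightweight single-band raster grids on a shared regular lon/lat grid.

All layers in a study share one :class:`Grid` (WGS84 decimal degrees,
row 0 = northernmost row, column 0 = westernmost column).  Values are
float64 with NaN as nodata.  Rasters are (de)serialised as ESRI ASCII
grids (``.asc``), a plain-text format read by every GIS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Grid", "RasterGrid", "read_ascii", "write_ascii"]


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular lon/lat grid.

    Parameters
    ----------
    west, south : float
        Coordinates of the outer (lower-left) grid corner, decimal degrees.
    resolution : float
        Cell size in degrees (square cells).
    nrows, ncols : int
        Grid shape; row 0 is the northernmost row.
    """

    west: float
    south: float
    resolution: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.resolution

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, length ``ncols``."""
        return self.west + (np.arange(self.ncols) + 0.5) * self.resolution

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, length ``nrows`` (north to south)."""
        return self.north - (np.arange(self.nrows) + 0.5) * self.resolution

    def center_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D arrays of cell-center (lon, lat) with the grid's shape."""
        lon = np.broadcast_to(self.lon_centers, self.shape)
        lat = np.broadcast_to(self.lat_centers[:, None], self.shape)
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Return the (row, col) of the cell containing a point.

        Half-open convention: a point on a shared edge belongs to the cell
        to its east (for a meridian edge) / north (for a parallel edge).
        """
        if not (self.west <= lon < self.east) or not (self.south < lat <= self.north):
            raise ValueError(
                f"point ({lon}, {lat}) outside grid "
                f"[{self.west}, {self.east}) x ({self.south}, {self.north}]"
            )
        col = int(math.floor((lon - self.west) / self.resolution))
        t = (self.north - lat) / self.resolution
        row = max(int(math.ceil(t)) - 1, 0)
        col = min(col, self.ncols - 1)
        row = min(row, self.nrows - 1)
        return row, col


@dataclass
class RasterGrid:
    """A named single-band layer: values (NaN = nodata) on a shared grid."""

    name: str
    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of valid (non-nodata) cells."""
        return np.isfinite(self.values)

    def copy(self, name: str | None = None, values: np.ndarray | None = None) -> "RasterGrid":
        return RasterGrid(
            name=self.name if name is None else name,
            grid=self.grid,
            values=self.values.copy() if values is None else np.asarray(values, float),
        )


_NODATA = -9999.0


def write_ascii(raster: RasterGrid, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (text, NODATA_value -9999)."""
    path = Path(path)
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    g = raster.grid
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.west:.10g}\n")
        fh.write(f"yllcorner {g.south:.10g}\n")
        fh.write(f"cellsize {g.resolution:.10g}\n")
        fh.write(f"NODATA_value {_NODATA:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_ascii(path: str | Path, name: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii`."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= header.keys():
        raise ValueError(f"{path}: missing ASCII-grid header keys {required - header.keys()}")
    grid = Grid(
        west=header["xllcorner"],
        south=header["yllcorner"],
        resolution=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
    )
    values = np.array(rows, dtype=float)
    nodata = header.get("nodata_value", _NODATA)
    values[values == nodata] = np.nan
    return RasterGrid(name=name or path.stem, grid=grid, values=values)
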