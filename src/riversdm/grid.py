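"""Geographic grid geometry and single-band raster containers.

Everything in this package lives on a plain geographic (lon/lat, WGS84)
grid.  The conventions are fixed once here and relied on everywhere:

* row 0 is the northernmost row; column 0 the westernmost column;
* a cell's value refers to its center;
* a point (lon, lat) maps to the cell containing it under half-open
  intervals [west, east) in longitude and (south, north] in latitude.

Rasters are held as float arrays with NaN marking nodata.  On-disk format
is the ESRI ASCII grid (``.asc``), a plain-text single-band format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular lon/lat grid: origin at the north-west corner.

    Parameters
    ----------
    west, north : float
        Coordinates of the outer corner of cell (0, 0), in decimal degrees.
    cellsize : float
        Cell width and height in decimal degrees (square cells).
    nrows, ncols : int
        Grid dimensions.
    """

    west: float
    north: float
    cellsize: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cellsize

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cellsize

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.west + (col + 0.5) * self.cellsize
        lat = self.north - (row + 0.5) * self.cellsize
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (lon, lat) of all cell centers, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        lon = self.west + (cols + 0.5) * self.cellsize
        lat = self.north - (rows + 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def locate(self, lon: float, lat: float) -> tuple[int, int]:
        """Map a point to its (row, col); raise if outside the extent.

        Longitude intervals are half-open [west, east); latitude intervals
        are (south, north], so a point on the northern edge of a cell
        belongs to that cell.
        """
        if not (self.west <= lon < self.east):
            raise ValueError(f"longitude {lon} outside [{self.west}, {self.east})")
        if not (self.south < lat <= self.north):
            raise ValueError(f"latitude {lat} outside ({self.south}, {self.north}]")
        # the 1e-9 guard keeps points that sit exactly on a cell edge (up to
        # float rounding) on the side the half-open conventions dictate
        col = int(math.floor((lon - self.west) / self.cellsize + 1e-9))
        # floor keeps a cell's southern edge out and its northern edge in,
        # matching the (south, north] convention
        row = int(math.floor((self.north - lat) / self.cellsize + 1e-9))
        row = min(max(row, 0), self.nrows - 1)
        col = min(col, self.ncols - 1)
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        return (self.west <= lon < self.east) and (self.south < lat <= self.north)


@dataclass
class Raster:
    """A single-band grid: float data with NaN as nodata."""

    data: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.data)

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data, dtype=float), self.geometry)


def read_ascii_grid(path: str | Path, nodata_default: float = -9999.0) -> Raster:
    """Read an ESRI ASCII grid (.asc) file into a :class:`Raster`."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                       "yllcenter", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        west = header["xllcorner"]
        south = header["yllcorner"]
    else:
        west = header["xllcenter"] - cellsize / 2
        south = header["yllcenter"] - cellsize / 2
    nodata = header.get("nodata_value", nodata_default)
    data = np.concatenate(rows).reshape(nrows, ncols)
    data[data == nodata] = np.nan
    geom = GridGeometry(west=west, north=south + nrows * cellsize,
                        cellsize=cellsize, nrows=nrows, ncols=ncols)
    return Raster(data, geom)


def write_ascii_grid(raster: Raster, path: str | Path,
                     nodata: float = -9999.0, fmt: str = "%.8g") -> None:
    """Write a :class:`Raster` as an ESRI ASCII grid (.asc) file."""
    g = raster.geometry
    data = raster.data.copy()
    data[np.isnan(data)] = nodata
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.west!r}\n")
        fh.write(f"yllcorner {g.south!r}\n")
        fh.write(f"cellsize {g.cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in data:
            fh.write(" ".join(fmt % v for v in row) + "\n")
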