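"""Single-band georeferenced raster grids.

``RasterGrid`` is the carrier used throughout the package for covariates,
suitability, resistance, kernel and corridor surfaces.  Values are stored as
a float64 array with ``nan`` marking nodata; the grid lives in a projected
planar coordinate system (meters), north-up, row 0 at the north edge, with
cell values referring to cell centers.

Rasters round-trip through the ESRI ASCII grid format (``.asc``), a plain
text format readable by GDAL, QGIS and ArcGIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid"]

_NODATA_OUT = -9999.0


@dataclass
class RasterGrid:
    """A single-band raster on a square-celled, north-up projected grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; ``nan`` is nodata.  Stored as float64.
    cell_size : float
        Cell edge length in meters.
    origin : (float, float)
        ``(x_west, y_north)`` — coordinates of the outer corner of the
        top-left cell.
    crs : str
        Free-text tag for the projected CRS (e.g. ``"EPSG:32648"``).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "local-projected-m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        x0, y1 = self.origin
        return (x0, y1 - self.nrows * self.cell_size,
                x0 + self.ncols * self.cell_size, y1)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~np.isnan(self.values)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def xy(self, row: np.ndarray | int, col: np.ndarray | int):
        """Center coordinates of cell(s) at (row, col)."""
        x0, y1 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y1 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def index(self, x: np.ndarray | float, y: np.ndarray | float):
        """Row/col of the cell containing point(s) (x, y)."""
        x0, y1 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y1 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def cell_centers(self):
        """Meshgrid arrays (X, Y) of all cell-center coordinates."""
        rows = np.arange(self.nrows)
        cols = np.arange(self.ncols)
        cgrid, rgrid = np.meshgrid(cols, rows)
        return self.xy(rgrid, cgrid)

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def sample(self, x, y) -> np.ndarray:
        """Value of the cell containing each point (nearest-cell lookup)."""
        row, col = self.index(x, y)
        row = np.clip(row, 0, self.nrows - 1)
        col = np.clip(col, 0, self.ncols - 1)
        return self.values[row, col]

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's geometry."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("shape mismatch with template grid")
        return RasterGrid(values, self.cell_size, self.origin, self.crs)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.cell_size, other.cell_size)
                and np.allclose(self.origin, other.origin))

    # ------------------------------------------------------------------
    # I/O  (ESRI ASCII grid)
    # ------------------------------------------------------------------
    def to_ascii(self, path: str | Path) -> None:
        path = Path(path)
        vals = np.where(np.isnan(self.values), _NODATA_OUT, self.values)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.bounds[0]:.6f}\n"
            f"yllcorner {self.bounds[1]:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {_NODATA_OUT}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def from_ascii(cls, path: str | Path, crs: str = "local-projected-m") -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        if data.shape != (nrows, ncols):
            data = data.reshape(nrows, ncols)
        cell = header["cellsize"]
        nodata = header.get("nodata_value", _NODATA_OUT)
        data = np.where(data == nodata, np.nan, data)
        origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
        return cls(data, cell, origin, crs)
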