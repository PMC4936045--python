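"""Planar raster grids and plain-text raster I/O.

All spatial data in this package live on a single planar grid of square
cells (default 25 m, the resolution at which landscape covariates are
defined).  Rasters are numpy arrays indexed ``[row, col]`` with row 0 at
the *bottom* of the extent; the ESRI-ASCII writer flips rows so files are
top-down as the format requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "write_ascii_grid", "read_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid: origin (lower-left corner), cell size, shape."""

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 25.0
    n_rows: int = 400
    n_cols: int = 400

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, shape (n_rows, n_cols)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x, y):
        """Cell (row, col) containing planar points, half-open rule [edge, edge+cell).

        Raises ValueError naming the first offending point outside the extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            i = int(np.argmax(np.atleast_1d(bad)))
            bx = float(np.atleast_1d(x)[i])
            by = float(np.atleast_1d(y)[i])
            raise ValueError(f"point ({bx:.1f}, {by:.1f}) lies outside the grid extent")
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)


def write_ascii_grid(path, grid: GridSpec, values: np.ndarray, nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI-ASCII grid (text, top-down row order)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("raster shape does not match the grid")
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x}\n"
        f"yllcorner {grid.origin_y}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.8g")


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI-ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
    )
    data = np.atleast_2d(data)[::-1]
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return grid, data
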