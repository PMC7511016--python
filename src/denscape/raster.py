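"""Planar single-band raster container and plain-text I/O.

All rasters in the pipeline share one projected planar coordinate system in
metres.  A :class:`Grid` stores a 2-D value matrix (row 0 = northernmost row),
the cell size, and the coordinates of the north-west corner.  Nodata is
represented as NaN in memory and as ``-9999`` in the ESRI ASCII grid files
used for on-disk exchange.

Cell membership is half-open: cell (r, c) covers
``[x0 + c*cs, x0 + (c+1)*cs)`` in x and ``(y0 - (r+1)*cs, y0 - r*cs]`` in y,
so a point on a shared edge belongs to exactly one cell and point -> cell
lookup is the exact inverse of the within-cell jitter used by the landscape
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Grid:
    """Georeferenced single-band raster.

    Parameters
    ----------
    data
        2-D float array, row 0 at the top (north). NaN marks nodata.
    cell_size
        Cell edge length in metres (> 0).
    x0, y0
        Coordinates of the north-west corner of the raster (west edge of
        column 0, north edge of row 0).
    """

    data: np.ndarray
    cell_size: float = 5.0
    x0: float = 0.0
    y0: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Grid data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.y0 is None:
            # default origin: south-west corner at (0, 0)
            self.y0 = self.data.shape[0] * self.cell_size

    # ---- basic geometry ------------------------------------------------
    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_area(self) -> float:
        """Cell area in m^2."""
        return self.cell_size ** 2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.x0,
            self.y0 - self.ny * self.cell_size,
            self.x0 + self.nx * self.cell_size,
            self.y0,
        )

    def like(self, data: np.ndarray) -> "Grid":
        """New Grid sharing this grid's georeferencing."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise ValueError("shape mismatch")
        return Grid(data, self.cell_size, self.x0, self.y0)

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
        )

    # ---- point <-> cell ------------------------------------------------
    def rowcol(self, x, y):
        """Cells containing points (half-open convention; vectorized).

        Points on the north edge of the raster belong to row 0; points on
        the west edge of a column belong to that column.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        # row r covers (y0-(r+1)cs, y0-r*cs]; y = y0-r*cs maps to ty = r,
        # so plain floor realises the half-open convention on both axes.
        row = np.floor((self.y0 - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y):
        """Boolean mask of points inside the raster footprint."""
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y0 - (row + 0.5) * self.cell_size
        return x, y

    def center_coords(self):
        """Meshgrid arrays (X, Y) of all cell-centre coordinates."""
        cols = np.arange(self.nx)
        rows = np.arange(self.ny)
        x = self.x0 + (cols + 0.5) * self.cell_size
        y = self.y0 - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def sample(self, x, y):
        """Values at the cells containing the points; NaN outside extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        out = np.full(x.shape, np.nan)
        if np.any(inside):
            r, c = self.rowcol(x[inside], y[inside])
            out[inside] = self.data[r, c]
        return out


def require_aligned(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise ValueError("grids are not aligned (shape/origin/cell size differ)")


# ---- ESRI ASCII grid I/O ----------------------------------------------

def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a Grid as an ESRI ASCII raster (plain text, nodata -9999)."""
    path = Path(path)
    data = np.where(np.isfinite(grid.data), grid.data, NODATA)
    header = (
        f"ncols {grid.nx}\n"
        f"nrows {grid.ny}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0 - grid.ny * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    cs = header["cellsize"]
    y0 = header["yllcorner"] + header["nrows"] * cs
    return Grid(data, cs, header["xllcorner"], y0)
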