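"""Minimal planar raster container with ESRI ASCII grid I/O.

Rasters are stored row-major with row 0 at the top (largest y), matching the
on-disk layout of the ESRI ASCII grid format. All coordinates are planar and
in meters; no geographic CRS math is performed anywhere in the package.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Grid"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class Grid:
    """A single-band raster on a regular square-cell grid.

    Parameters
    ----------
    data : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the northernmost row.
    cellsize : float
        Cell edge length in meters.
    xllcorner, yllcorner : float
        Coordinates of the lower-left corner of the lower-left cell.
    nodata : float
        Sentinel for unclassified cells.
    """

    data: np.ndarray
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Grid data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def x_centers(self) -> np.ndarray:
        """x coordinate of each column's cell centers (ascending)."""
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def y_centers(self) -> np.ndarray:
        """y coordinate of each row's cell centers, row 0 first (descending)."""
        return self.yllcorner + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of cell-center coordinates, shape (nrows, ncols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing points (x, y)."""
        col = np.floor((np.asarray(x) - self.xllcorner) / self.cellsize).astype(int)
        row = self.nrows - 1 - np.floor(
            (np.asarray(y) - self.yllcorner) / self.cellsize
        ).astype(int)
        return row, col

    def copy(self) -> "Grid":
        return Grid(self.data.copy(), self.cellsize, self.xllcorner, self.yllcorner, self.nodata)

    # -- I/O --------------------------------------------------------------
    def write_ascii(self, path: str | Path, fmt: str | None = None) -> None:
        """Write the grid as an ESRI ASCII file (deterministic byte layout)."""
        if fmt is None:
            fmt = "%d" if np.issubdtype(self.data.dtype, np.integer) else "%.6f"
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xllcorner:.6f}\n")
            fh.write(f"yllcorner {self.yllcorner:.6f}\n")
            fh.write(f"cellsize {self.cellsize:.6f}\n")
            fh.write(f"NODATA_value {self.nodata:g}\n")
            np.savetxt(fh, self.data, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Grid":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                    header[parts[0].lower()] = float(parts[1])
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        if int(header["nrows"]) == 1 and data.shape[0] != 1:
            data = data.reshape(1, -1)
        integral = np.all(np.mod(data, 1) == 0)
        if integral:
            data = data.astype(int)
        return cls(
            data=data,
            cellsize=header["cellsize"],
            xllcorner=header.get("xllcorner", 0.0),
            yllcorner=header.get("yllcorner", 0.0),
            nodata=header.get("nodata_value", -9999.0),
        )
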