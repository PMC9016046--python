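"""Raster grids and ESRI ASCII grid interchange.

A :class:`RasterGrid` is a plain row-major lattice ordered north-to-south,
west-to-east, with cell-center value semantics.  The ESRI ASCII grid format
(``.asc``) is used for all raster interchange (the 10 m DEM input and the
100 m interpolated change surfaces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RasterGrid", "RasterFormatError", "read_raster_ascii", "write_raster_ascii"]

DEFAULT_NODATA = -9999.0


class RasterFormatError(ValueError):
    """Malformed ESRI ASCII grid header or body."""


@dataclass
class RasterGrid:
    """A regular raster; ``values[0, 0]`` is the north-west cell.

    Parameters
    ----------
    xll_m, yll_m:
        Coordinates of the lower-left corner of the lower-left cell, in m.
    cellsize_m:
        Square cell edge length in m.
    nodata_value:
        Sentinel stored on disk; in memory nodata cells are ``nan``.
    """

    values: np.ndarray
    xll_m: float = 0.0
    yll_m: float = 0.0
    cellsize_m: float = 1.0
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D lattice")
        if self.cellsize_m <= 0:
            raise ValueError("cellsize_m must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, shaped like ``values``."""
        cs = self.cellsize_m
        x = self.xll_m + (np.arange(self.ncols) + 0.5) * cs
        y = self.yll_m + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        return np.meshgrid(x, y)

    def cell_index(self, x: float | np.ndarray, y: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing planar point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.xll_m) / self.cellsize_m).astype(int)
        row = self.nrows - 1 - np.floor((np.asarray(y) - self.yll_m) / self.cellsize_m).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_index(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def sample(self, x, y) -> np.ndarray:
        """Value of the cell under each point; points must lie inside."""
        row, col = self.cell_index(x, y)
        # points exactly on the top/right edge belong to the edge cell
        row = np.clip(row, 0, self.nrows - 1)
        col = np.clip(col, 0, self.ncols - 1)
        return self.values[row, col]


def read_raster_ascii(path) -> RasterGrid:
    """Read an ESRI ASCII grid; nodata cells become ``nan``."""
    with open(path) as fh:
        header: dict[str, float] = {}
        required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        missing = required - header.keys()
        if missing:
            raise RasterFormatError(f"ASCII grid header missing keys: {sorted(missing)}")
        fh.seek(pos)
        body = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if body.shape != (nrows, ncols):
        raise RasterFormatError(
            f"data block is {body.shape[0]}x{body.shape[1]}, header says {nrows}x{ncols}"
        )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.where(np.isclose(body, nodata), np.nan, body)
    return RasterGrid(values, header["xllcorner"], header["yllcorner"], header["cellsize"], nodata)


def write_raster_ascii(grid: RasterGrid, path) -> None:
    """Write a grid as an ESRI ASCII file; ``nan`` cells become the nodata sentinel."""
    body = np.where(np.isnan(grid.values), grid.nodata_value, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll_m:.6f}\n")
        fh.write(f"yllcorner {grid.yll_m:.6f}\n")
        fh.write(f"cellsize {grid.cellsize_m:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata_value:g}\n")
        np.savetxt(fh, body, fmt="%.10g")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
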