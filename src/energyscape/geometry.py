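"""Planar grid geometry shared by all raster layers.

All grids are row-major numpy arrays indexed ``[iy, ix]`` with row 0 at the
*southern* edge (y increasing with row index).  Coordinates are planar meters;
no CRS handling beyond that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "write_ascii_grid", "read_ascii_grid"]


@dataclass(frozen=True)
class GridGeometry:
    """Origin (lower-left corner), square cell size (m) and shape of a grid."""

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid's outer edges."""
        return (
            self.x0,
            self.x0 + self.nx * self.cell_size,
            self.y0,
            self.y0 + self.ny * self.cell_size,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def contains(self, x, y) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def world_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to (iy, ix) cell indices.

        Raises ValueError if any point falls outside the grid.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.all(self.contains(x, y)):
            raise ValueError("coordinates outside grid extent")
        ix = np.floor((x - self.x0) / self.cell_size).astype(np.intp)
        iy = np.floor((y - self.y0) / self.cell_size).astype(np.intp)
        return iy, ix

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-center coordinates (ys of length ny, xs of nx)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return ys, xs

    def center_meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        ys, xs = self.cell_centers()
        return np.meshgrid(xs, ys)  # (X, Y) each shaped (ny, nx)

    def to_dict(self) -> dict:
        return {
            "x0": self.x0,
            "y0": self.y0,
            "cell_size": self.cell_size,
            "nx": self.nx,
            "ny": self.ny,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            x0=float(d["x0"]),
            y0=float(d["y0"]),
            cell_size=float(d["cell_size"]),
            nx=int(d["nx"]),
            ny=int(d["ny"]),
        )


def write_ascii_grid(path, grid: np.ndarray, geom: GridGeometry, nodata: float = -9999.0) -> None:
    """Write a single-band grid as an ESRI ASCII raster with a JSON sidecar.

    The ASCII format stores rows north-to-south, so the array (row 0 = south)
    is flipped on write and on read.
    """
    path = Path(path)
    grid = np.asarray(grid, dtype=float)
    if grid.shape != geom.shape:
        raise ValueError("grid shape does not match geometry")
    out = np.where(np.isfinite(grid), grid, nodata)
    header = (
        f"ncols {geom.nx}\nnrows {geom.ny}\n"
        f"xllcorner {geom.x0!r}\nyllcorner {geom.y0!r}\n"
        f"cellsize {geom.cell_size!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(geom.to_dict(), fh, sort_keys=True)
        fh.write("\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry]:
    path = Path(path)
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    geom = GridGeometry(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        nx=int(header["ncols"]),
        ny=int(header["nrows"]),
    )
    grid = np.atleast_2d(data)[::-1].copy()
    nodata = header["nodata_value"]
    grid[grid == nodata] = np.nan
    return grid, geom
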