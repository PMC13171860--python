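"""Raster plumbing: the 30 m analysis lattice, value arrays and ASCII-grid I/O.

All layers in a run share one :class:`GridSpec`. The convention is a
north-up projected grid: x grows with column index, y *decreases* with row
index, and the point associated with cell ``(r, c)`` is its center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "Raster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster lattice.

    ``(origin_x, origin_y)`` is the map coordinate of the upper-left corner
    of the upper-left cell; ``cell_size`` is in meters.
    """

    origin_x: float
    origin_y: float
    cell_size: float = 30.0
    n_rows: int = 1
    n_cols: int = 1
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def width_m(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height_m(self) -> float:
        return self.n_rows * self.cell_size

    def cell_center(self, row, col):
        """Map coordinates of the center(s) of cell(s) ``(row, col)``."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def cell_of(self, x, y):
        """Row/col indices of the cell containing map point(s) ``(x, y)``.

        Points outside the extent get out-of-range indices; callers decide
        whether to clip or drop.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y):
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def center_mesh(self):
        """(xs, ys) arrays of all cell-center coordinates, shape (n_rows, n_cols)."""
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        return self.cell_center(rows, cols)


@dataclass
class Raster:
    """A single-band georeferenced array with a nodata sentinel."""

    grid: GridSpec
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return (self.values != self.nodata) & np.isfinite(self.values)

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[~self.valid_mask] = np.nan
        return out

    def sample(self, x, y):
        """Nearest (cell-center) lookup at map points; outside extent -> NaN."""
        row, col = self.grid.cell_of(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        out = np.full(row.shape, np.nan)
        ok = (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        vals = self.values[row[ok], col[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out if out.size > 1 else float(out[0])

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.grid, values, self.nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (plain text, georeferenced via the header)."""
    g = raster.grid
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - g.height_m!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = raster.nodata
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, crs_tag: str = "") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any tool)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                meta[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    n_rows = int(meta["nrows"])
    n_cols = int(meta["ncols"])
    cell = meta["cellsize"]
    grid = GridSpec(
        origin_x=meta["xllcorner"],
        origin_y=meta["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_tag=crs_tag,
    )
    nodata = meta.get("nodata_value", DEFAULT_NODATA)
    return Raster(grid, values, nodata)
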