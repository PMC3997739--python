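"""Planar raster grid with square cells and NaN no-data.

Coordinates are planar metres.  The grid origin ``(x0, y0)`` is the
lower-left corner of cell ``(row=0, col=0)``; rows increase northward,
columns eastward.  Cell footprints are half-open,
``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s)``, so every point in
the extent belongs to exactly one cell and points on the max edge fall
outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: origin, cell size and shape."""

    x0: float
    y0: float
    cell_size: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid shape must be positive")

    @property
    def width(self) -> float:
        return self.cols * self.cell_size

    @property
    def height(self) -> float:
        return self.rows * self.cell_size

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x0 <= x < self.x0 + self.width
            and self.y0 <= y < self.y0 + self.height
        )

    def assign_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col) under the half-open convention."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        col = int(np.floor((x - self.x0) / self.cell_size))
        row = int(np.floor((y - self.y0) / self.cell_size))
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of shape (rows, cols) with cell-center coords."""
        xs = self.x0 + (np.arange(self.cols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class Grid:
    """A raster layer: 2-D float data on a :class:`GridSpec`, NaN = no-data."""

    data: np.ndarray
    spec: GridSpec
    name: str = field(default="")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.spec.rows, self.spec.cols):
            raise ValueError(
                f"data shape {self.data.shape} does not match spec "
                f"({self.spec.rows}, {self.spec.cols})"
            )

    @classmethod
    def full(cls, spec: GridSpec, value: float = np.nan, name: str = "") -> "Grid":
        return cls(np.full((spec.rows, spec.cols), value, dtype=float), spec, name)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def copy_with(self, data: np.ndarray, name: str | None = None) -> "Grid":
        return Grid(np.asarray(data, dtype=float), self.spec, name if name is not None else self.name)

    def value_at(self, x: float, y: float) -> float:
        row, col = self.spec.assign_cell(x, y)
        return float(self.data[row, col])

    def same_geometry(self, other: "Grid") -> bool:
        return self.spec == other.spec

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, path) -> None:
        """Write as ESRI ASCII grid (row order flipped to north-up)."""
        header = (
            f"ncols {self.spec.cols}\n"
            f"nrows {self.spec.rows}\n"
            f"xllcorner {self.spec.x0}\n"
            f"yllcorner {self.spec.y0}\n"
            f"cellsize {self.spec.cell_size}\n"
            f"NODATA_value {NODATA}\n"
        )
        out = np.where(np.isfinite(self.data), self.data, NODATA)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out[::-1], fmt="%.10g")

    @classmethod
    def read_ascii(cls, path, name: str = "") -> "Grid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                header[key.lower()] = float(value)
            body = np.loadtxt(fh)
        spec = GridSpec(
            x0=header["xllcorner"],
            y0=header["yllcorner"],
            cell_size=header["cellsize"],
            rows=int(header["nrows"]),
            cols=int(header["ncols"]),
        )
        body = np.atleast_2d(body)[::-1]
        nodata = header.get("nodata_value", NODATA)
        data = np.where(body == nodata, np.nan, body)
        return cls(data, spec, name)


def resample_nearest(source: Grid, target_spec: GridSpec) -> Grid:
    """Resample ``source`` onto ``target_spec`` by nearest-neighbour lookup.

    Each target cell takes the value of the source cell containing (or
    nearest to, when outside the source extent) the target cell center.
    """
    tx, ty = target_spec.cell_centers()
    col = np.floor((tx - source.spec.x0) / source.spec.cell_size).astype(int)
    row = np.floor((ty - source.spec.y0) / source.spec.cell_size).astype(int)
    col = np.clip(col, 0, source.spec.cols - 1)
    row = np.clip(row, 0, source.spec.rows - 1)
    return Grid(source.data[row, col], target_spec, source.name)


def block_aggregate(grid: Grid, factor: int, how: str = "mean") -> Grid:
    """Aggregate a grid by an integer ``factor`` per axis (trailing remainder
    rows/columns are dropped)."""
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    rows = (grid.spec.rows // factor) * factor
    cols = (grid.spec.cols // factor) * factor
    if rows == 0 or cols == 0:
        raise ValueError("grid too small for aggregation factor")
    block = grid.data[:rows, :cols].reshape(rows // factor, factor, cols // factor, factor)
    if how == "mean":
        agg = np.nanmean(block, axis=(1, 3))
    elif how == "sum":
        agg = np.nansum(block, axis=(1, 3))
    else:
        raise ValueError(f"unknown aggregation {how!r}")
    spec = GridSpec(
        x0=grid.spec.x0,
        y0=grid.spec.y0,
        cell_size=grid.spec.cell_size * factor,
        rows=rows // factor,
        cols=cols // factor,
    )
    return Grid(agg, spec, grid.name)
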