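"""Sounding cleaning, gridding with coarse infill, and multi-window Horn slope.

Depths are metres, positive down.  The gridder replaces spline interpolation
with a per-cell median plus nearest-neighbour infill from a coarse reference
grid: deterministic, and sufficient for everything computed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import Grid, GridSpec, block_aggregate, resample_nearest

DEFAULT_SLOPE_WINDOWS_M = (1_000.0, 5_000.0, 10_000.0, 20_000.0)
#: alternate multi-scale window set supported by configuration
ALT_SLOPE_WINDOWS_M = (500.0, 1_000.0, 2_500.0, 5_000.0, 20_000.0)


@dataclass
class SoundingSet:
    """Scattered depth soundings as an (n, 3) array of (x, y, depth)."""

    points: np.ndarray
    audit: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TerrainLayer:
    slope: Grid
    window_size: float


def clean_soundings(raw: SoundingSet, extent: GridSpec | None = None) -> SoundingSet:
    """Drop non-finite rows, non-positive depths and (optionally) points
    outside a target extent; record per-rule removal counts."""
    pts = raw.points
    audit = {"nonfinite": 0, "nonpositive_depth": 0, "out_of_extent": 0}
    finite = np.all(np.isfinite(pts), axis=1)
    audit["nonfinite"] = int((~finite).sum())
    pts = pts[finite]
    positive = pts[:, 2] > 0
    audit["nonpositive_depth"] = int((~positive).sum())
    pts = pts[positive]
    if extent is not None:
        inside = (
            (pts[:, 0] >= extent.x0)
            & (pts[:, 0] < extent.x0 + extent.width)
            & (pts[:, 1] >= extent.y0)
            & (pts[:, 1] < extent.y0 + extent.height)
        )
        audit["out_of_extent"] = int((~inside).sum())
        pts = pts[inside]
    return SoundingSet(pts, audit)


def grid_soundings(
    soundings: SoundingSet,
    grid_spec: GridSpec,
    infill: Grid | None = None,
) -> tuple[Grid, dict]:
    """Grid soundings to ``grid_spec`` by per-cell median, then fill empty
    cells from a coarse ``infill`` grid resampled by nearest neighbour.

    Returns the bathymetry grid and a report with the fraction of cells
    directly constrained by soundings.
    """
    pts = soundings.points
    data = np.full((grid_spec.rows, grid_spec.cols), np.nan)
    if len(pts):
        col = np.floor((pts[:, 0] - grid_spec.x0) / grid_spec.cell_size).astype(int)
        row = np.floor((pts[:, 1] - grid_spec.y0) / grid_spec.cell_size).astype(int)
        inside = (row >= 0) & (row < grid_spec.rows) & (col >= 0) & (col < grid_spec.cols)
        row, col, depth = row[inside], col[inside], pts[inside, 2]
        flat = row * grid_spec.cols + col
        order = np.argsort(flat, kind="stable")
        flat, depth = flat[order], depth[order]
        uniq, start = np.unique(flat, return_index=True)
        for cell, lo, hi in zip(uniq, start, np.append(start[1:], len(flat))):
            data[cell // grid_spec.cols, cell % grid_spec.cols] = np.median(depth[lo:hi])
    constrained = np.isfinite(data)
    if infill is not None:
        if (
            infill.spec.x0 > grid_spec.x0
            or infill.spec.y0 > grid_spec.y0
            or infill.spec.x0 + infill.spec.width < grid_spec.x0 + grid_spec.width
            or infill.spec.y0 + infill.spec.height < grid_spec.y0 + grid_spec.height
        ):
            raise ValueError("infill grid does not cover the target extent")
        filled = resample_nearest(infill, grid_spec)
        data = np.where(constrained, data, filled.data)
    report = {
        "n_soundings": int(len(pts)),
        "fraction_constrained": float(constrained.mean()),
        "n_cells_infilled": int((np.isfinite(data) & ~constrained).sum()),
    }
    return Grid(data, grid_spec, "bathymetry"), report


def _horn_gradients(z: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn's 8-neighbour weighted finite differences; NaN on the border and
    wherever the 3x3 window touches no-data."""
    gx = np.full_like(z, np.nan)
    gy = np.full_like(z, np.nan)
    if z.shape[0] < 3 or z.shape[1] < 3:
        return gx, gy
    c = np.s_[1:-1]
    nw, n_, ne = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    w_, e_ = z[c, :-2], z[c, 2:]
    sw, s_, se = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    gx[c, c] = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * spacing)
    gy[c, c] = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * spacing)
    return gx, gy


def horn_slope(bathymetry: Grid, window: float) -> TerrainLayer:
    """Slope in degrees from Horn's algorithm at a given window scale.

    The grid is block-mean aggregated so one coarse cell spans ``window``
    metres, gradients are computed on the aggregate, and slopes are assigned
    back to the constituent fine cells.  A window equal to the cell size is
    plain Horn slope on the native grid.
    """
    cell = bathymetry.spec.cell_size
    if window < cell:
        raise ValueError(f"window {window} smaller than cell size {cell}")
    factor = max(1, int(round(window / cell)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        coarse = bathymetry if factor == 1 else block_aggregate(bathymetry, factor, "mean")
    gx, gy = _horn_gradients(coarse.data, coarse.spec.cell_size)
    slope_coarse = np.degrees(np.arctan(np.hypot(gx, gy)))
    out = np.full((bathymetry.spec.rows, bathymetry.spec.cols), np.nan)
    rows_c, cols_c = slope_coarse.shape
    out[: rows_c * factor, : cols_c * factor] = np.kron(
        slope_coarse, np.ones((factor, factor))
    )
    out[~bathymetry.valid_mask] = np.nan
    grid = Grid(out, bathymetry.spec, f"slope_{int(window)}m")
    return TerrainLayer(slope=grid, window_size=float(factor * cell))
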