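"""Post-model overlap accounting: suitability area inside polygons, substrate
cross-tabulation, trawl-line density with a privacy mask, trawl intensity by
suitability class, and presence-niche summaries.

Cell membership in a polygon is decided by the cell center (no partial-cell
weighting), so every area is cell count x cell area and can be checked
against a brute-force per-cell oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

from .grid import Grid, GridSpec
from .spatial_cv import ConsensusGrid

KM2_PER_NM2 = 3.429904  # 1.852^2

SUBSTRATE_SOFT = 0
SUBSTRATE_MIXED = 1
SUBSTRATE_HARD = 2
SUBSTRATE_NAMES = {SUBSTRATE_HARD: "hard", SUBSTRATE_MIXED: "mixed", SUBSTRATE_SOFT: "soft"}


@dataclass
class TrawlIntensityGrid:
    """km of trawl line per km^2, NaN where masked for privacy or no-data."""

    grid: Grid
    radius: float
    n_masked: int


def zonal_area(
    consensus: ConsensusGrid,
    polygons: dict[str, BaseGeometry],
    cell_area_km2: float | None = None,
) -> pd.DataFrame:
    """Area per suitability class inside each polygon (Table-5-style rows).

    Areas are reported in km^2 and nm^2; the "suitable" column counts classes
    > 0 with its percentage of the polygon-covered valid area.
    """
    grid = consensus.grid
    if cell_area_km2 is None:
        cell_area_km2 = (grid.spec.cell_size / 1000.0) ** 2
    cx, cy = grid.spec.cell_centers()
    valid = grid.valid_mask
    rows = []
    for name, geom in polygons.items():
        inside = contains_xy(geom, cx, cy) & valid
        if not inside.any():
            rows.append(
                {"polygon": name, "total_km2": 0.0, "total_nm2": 0.0,
                 **{f"class_{k}_km2": 0.0 for k in range(consensus.k + 1)},
                 **{f"class_{k}_nm2": 0.0 for k in range(consensus.k + 1)},
                 "suitable_km2": 0.0, "suitable_nm2": 0.0, "suitable_pct": 0.0}
            )
            continue
        values = grid.data[inside].astype(int)
        total = inside.sum() * cell_area_km2
        row: dict = {"polygon": name, "total_km2": total, "total_nm2": total / KM2_PER_NM2}
        suitable = 0.0
        for k in range(consensus.k + 1):
            area = (values == k).sum() * cell_area_km2
            row[f"class_{k}_km2"] = area
            row[f"class_{k}_nm2"] = area / KM2_PER_NM2
            if k > 0:
                suitable += area
        row["suitable_km2"] = suitable
        row["suitable_nm2"] = suitable / KM2_PER_NM2
        row["suitable_pct"] = 100.0 * suitable / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("polygon")


def resample_substrate_majority(substrate: Grid, target_spec: GridSpec) -> Grid:
    """Resample a finer substrate class raster to the analysis grid by
    majority rule; ties break hard > mixed > soft."""
    sx, sy = substrate.spec.cell_centers()
    inside = (
        (sx >= target_spec.x0) & (sx < target_spec.x0 + target_spec.width)
        & (sy >= target_spec.y0) & (sy < target_spec.y0 + target_spec.height)
        & substrate.valid_mask
    )
    col = np.floor((sx - target_spec.x0) / target_spec.cell_size).astype(int)
    row = np.floor((sy - target_spec.y0) / target_spec.cell_size).astype(int)
    counts = np.zeros((target_spec.rows, target_spec.cols, 3))
    for cls in (SUBSTRATE_SOFT, SUBSTRATE_MIXED, SUBSTRATE_HARD):
        sel = inside & (substrate.data == cls)
        np.add.at(counts[:, :, cls], (row[sel], col[sel]), 1)
    total = counts.sum(axis=2)
    # argmax over class order hard, mixed, soft implements the tie-break
    order = [SUBSTRATE_HARD, SUBSTRATE_MIXED, SUBSTRATE_SOFT]
    stacked = np.stack([counts[:, :, c] for c in order], axis=2)
    winner = np.take(order, np.argmax(stacked, axis=2)).astype(float)
    winner[total == 0] = np.nan
    return Grid(winner, target_spec, "substrate")


def substrate_cross_tab(consensus: ConsensusGrid, substrate: Grid) -> pd.DataFrame:
    """Percentage of each suitability class's cells falling in each substrate
    class.  ``substrate`` may be at a finer resolution (majority-resampled)."""
    if substrate.spec != consensus.grid.spec:
        substrate = resample_substrate_majority(substrate, consensus.grid.spec)
    valid = consensus.grid.valid_mask & substrate.valid_mask
    rows = []
    for k in range(consensus.k + 1):
        members = valid & (consensus.grid.data == k)
        n = members.sum()
        if n == 0:
            rows.append({"suitability": k, "hard_pct": np.nan, "mixed_pct": np.nan,
                         "soft_pct": np.nan, "n_cells": 0})
            continue
        sub = substrate.data[members]
        rows.append(
            {"suitability": k,
             "hard_pct": 100.0 * (sub == SUBSTRATE_HARD).mean(),
             "mixed_pct": 100.0 * (sub == SUBSTRATE_MIXED).mean(),
             "soft_pct": 100.0 * (sub == SUBSTRATE_SOFT).mean(),
             "n_cells": int(n)}
        )
    return pd.DataFrame(rows).set_index("suitability")


def _clip_segment_lengths(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    """Exact length of each segment's intersection with a disc (vectorised)."""
    d = p1 - p0
    f = p0 - center
    a = np.einsum("ij,ij->i", d, d)
    b = 2 * np.einsum("ij,ij->i", f, d)
    c = np.einsum("ij,ij->i", f, f) - radius**2
    out = np.zeros(len(p0))
    degenerate = a <= 0
    disc = b**2 - 4 * a * c
    ok = (~degenerate) & (disc > 0)
    if not ok.any():
        return out
    sq = np.sqrt(disc[ok])
    t0 = np.clip((-b[ok] - sq) / (2 * a[ok]), 0.0, 1.0)
    t1 = np.clip((-b[ok] + sq) / (2 * a[ok]), 0.0, 1.0)
    out[ok] = np.maximum(t1 - t0, 0.0) * np.sqrt(a[ok])
    return out


def trawl_line_density(
    lines: list[tuple[np.ndarray, object]],
    grid_spec: GridSpec,
    radius: float = 3_000.0,
    min_vessels: int = 3,
) -> TrawlIntensityGrid:
    """Summed trawl-line length within a ``radius`` neighbourhood of each cell
    center, as km of line per km^2 of neighbourhood disc.

    ``lines`` is a list of (vertices (n, 2) in metres, vessel_id).  Cells
    where fewer than ``min_vessels`` distinct vessels contribute are masked
    (set ``min_vessels=0`` to disable the privacy rule).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    segs_p0, segs_p1, seg_vessel = [], [], []
    for vertices, vessel in lines:
        v = np.asarray(vertices, dtype=float).reshape(-1, 2)
        for i in range(len(v) - 1):
            if np.allclose(v[i], v[i + 1]):
                continue  # degenerate zero-length segment
            segs_p0.append(v[i])
            segs_p1.append(v[i + 1])
            seg_vessel.append(vessel)
    disc_area_km2 = np.pi * (radius / 1000.0) ** 2
    data = np.zeros((grid_spec.rows, grid_spec.cols))
    n_masked = 0
    if segs_p0:
        p0 = np.asarray(segs_p0)
        p1 = np.asarray(segs_p1)
        vessels = np.asarray(seg_vessel, dtype=object)
        cx, cy = grid_spec.cell_centers()
        for r in range(grid_spec.rows):
            for c in range(grid_spec.cols):
                center = np.array([cx[r, c], cy[r, c]])
                lengths = _clip_segment_lengths(p0, p1, center, radius)
                contributing = lengths > 0
                if min_vessels > 0 and len(set(vessels[contributing])) < min_vessels:
                    data[r, c] = np.nan
                    n_masked += 1
                else:
                    data[r, c] = lengths[contributing].sum() / 1000.0 / disc_area_km2
    elif min_vessels > 0:
        data[:] = np.nan
        n_masked = data.size
    return TrawlIntensityGrid(
        Grid(data, grid_spec, "trawl_intensity"), radius=radius, n_masked=n_masked
    )


def intensity_by_class(
    consensus: ConsensusGrid,
    intensity: TrawlIntensityGrid,
    bins: np.ndarray,
) -> pd.DataFrame:
    """Joint cell counts of suitability class x trawl-intensity bin over
    unmasked, valid cells; marginals appended."""
    if intensity.grid.spec != consensus.grid.spec:
        raise ValueError("consensus and intensity grids must share geometry")
    bins = np.asarray(bins, dtype=float)
    valid = consensus.grid.valid_mask & intensity.grid.valid_mask
    classes = consensus.grid.data[valid].astype(int)
    values = intensity.grid.data[valid]
    table = np.zeros((consensus.k + 1, len(bins) - 1), dtype=int)
    for k in range(consensus.k + 1):
        hist, _ = np.histogram(values[classes == k], bins=bins)
        table[k] = hist
    frame = pd.DataFrame(
        table,
        index=pd.Index(range(consensus.k + 1), name="suitability"),
        columns=[f"[{bins[i]:g},{bins[i + 1]:g})" for i in range(len(bins) - 1)],
    )
    frame["row_total"] = frame.sum(axis=1)
    return frame


def niche_summary(
    presence_values: pd.DataFrame,
    ranges: dict[str, tuple[float, float]] | None = None,
    percentiles: tuple[float, ...] = (5, 25, 50, 75, 95),
    density_bins: int = 50,
    density_bandwidth: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-variable niche statistics at presence sites, plus a smoothed
    density trace per variable for bean-plot-style rendering.

    ``ranges`` maps variable -> [a, b); the summary reports the fraction of
    presences inside.  Rows with no finite intersections are empty.
    """
    rows = []
    traces: dict[str, pd.DataFrame] = {}
    for var in presence_values.columns:
        v = presence_values[var].to_numpy(dtype=float)
        finite = np.isfinite(v)
        row: dict = {"variable": var, "n": int(finite.sum()), "n_nodata": int((~finite).sum())}
        if finite.sum() == 0:
            rows.append(row)
            continue
        v = v[finite]
        row["min"] = float(v.min())
        row["max"] = float(v.max())
        for p in percentiles:
            row[f"p{p:g}"] = float(np.percentile(v, p))
        if ranges and var in ranges:
            a, b = ranges[var]
            row["range_lo"], row["range_hi"] = a, b
            row["fraction_in_range"] = float(((v >= a) & (v < b)).mean())
        hist, edges = np.histogram(v, bins=density_bins, density=True)
        traces[var] = pd.DataFrame(
            {"center": (edges[:-1] + edges[1:]) / 2,
             "density": gaussian_filter1d(hist, density_bandwidth)}
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable"), traces
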