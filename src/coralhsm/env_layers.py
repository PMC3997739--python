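"""Seafloor environmental layer construction from depth-binned climatologies.

A climatology arrives as one coarse horizontal grid per standard depth
level.  Each level is interpolated to an intermediate resolution by inverse
distance weighting, resampled to the bathymetry grid, and the seafloor layer
is assembled by giving every valid bathymetry cell the value of the depth
level nearest its depth (ties to the shallower level; depths beyond the
deepest level clamp to the deepest bin).  The per-cell source level is kept
as provenance, and layers can be validated against water-bottle casts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .grid import Grid, GridSpec, resample_nearest


@dataclass
class DepthBinnedField:
    """Coarse horizontal grids of one variable at ordered standard depths."""

    variable: str
    levels: np.ndarray
    grids: list[Grid]
    units: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if len(self.levels) != len(self.grids):
            raise ValueError("one grid required per depth level")
        if len(self.levels) == 0:
            raise ValueError("empty depth-binned field")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("depth levels must be strictly increasing")
        spec0 = self.grids[0].spec
        if any(g.spec != spec0 for g in self.grids):
            raise ValueError("all level grids must share one extent")


@dataclass
class SeafloorLayer:
    variable: str
    grid: Grid
    source_bin: np.ndarray  # per-cell level index, -1 where no-data
    units: str = ""


@dataclass
class BottleValidation:
    variable: str
    n: int
    r: float | None
    r2: float | None
    excluded: dict[str, int]
    pairs: pd.DataFrame = field(repr=False, default=None)


def interp_bin_idw(
    level_grid: Grid,
    target_spec: GridSpec,
    power: float = 2.0,
    max_neighbors: int = 8,
) -> Grid:
    """Inverse-distance-weighted interpolation of a coarse grid's valid cells
    onto ``target_spec`` cell centers.  An exact hit returns the source value."""
    valid = level_grid.valid_mask
    if not valid.any():
        raise ValueError("no valid source cells to interpolate from")
    sx, sy = level_grid.spec.cell_centers()
    src = np.column_stack([sx[valid], sy[valid]])
    vals = level_grid.data[valid]
    tx, ty = target_spec.cell_centers()
    targets = np.column_stack([tx.ravel(), ty.ravel()])
    k = min(max_neighbors, len(src))
    tree = cKDTree(src)
    dist, idx = tree.query(targets, k=k)
    dist = np.atleast_2d(dist.reshape(len(targets), k))
    idx = np.atleast_2d(idx.reshape(len(targets), k))
    exact = dist[:, 0] < 1e-9
    w = np.clip(dist, 1e-9, None) ** (-power)
    w /= w.sum(axis=1, keepdims=True)
    # anchored on the nearest value: exact when all neighbours agree
    near = vals[idx[:, 0]]
    out = near + np.einsum("ij,ij->i", w, vals[idx] - near[:, None])
    out[exact] = vals[idx[exact, 0]]
    return Grid(out.reshape(target_spec.rows, target_spec.cols), target_spec, level_grid.name)


def extrude_to_seafloor(
    field: DepthBinnedField,
    bathymetry: Grid,
    power: float = 2.0,
    max_neighbors: int = 8,
    intermediate_factor: int = 5,
) -> SeafloorLayer:
    """Merge non-overlapping depth bins into a continuous seafloor layer.

    ``intermediate_factor`` sets the IDW interpolation resolution as a
    multiple of the bathymetry cell size (the "usually 0.1 degree"
    intermediate step); the interpolated level is then resampled to the
    bathymetry grid by nearest neighbour.
    """
    spec = bathymetry.spec
    inter_spec = GridSpec(
        x0=spec.x0,
        y0=spec.y0,
        cell_size=spec.cell_size * intermediate_factor,
        rows=max(1, spec.rows // intermediate_factor),
        cols=max(1, spec.cols // intermediate_factor),
    )
    depth = bathymetry.data
    valid = bathymetry.valid_mask
    # nearest level per cell, ties to the shallower level (stable argmin)
    dists = np.abs(depth[..., None] - field.levels[None, None, :])
    bin_idx = np.argmin(dists, axis=-1)
    out = np.full_like(depth, np.nan)
    source = np.full(depth.shape, -1, dtype=int)
    for i in range(len(field.levels)):
        members = valid & (bin_idx == i)
        if not members.any():
            continue
        inter = interp_bin_idw(field.grids[i], inter_spec, power, max_neighbors)
        level_at_target = resample_nearest(inter, spec)
        out[members] = level_at_target.data[members]
        source[members] = i
    grid = Grid(out, spec, field.variable)
    return SeafloorLayer(variable=field.variable, grid=grid, source_bin=source, units=field.units)


def validate_with_bottles(
    layer: SeafloorLayer,
    casts: pd.DataFrame,
    bathymetry: Grid,
    min_year: int = 2001,
    depth_tolerance: float = 0.05,
) -> BottleValidation:
    """Compare a seafloor layer against bottle casts that plausibly sampled
    bottom water.

    Casts must be post-``min_year``, carry a bottom-depth flag, and have a
    sample depth within ``depth_tolerance`` (fractional) of the bathymetry at
    their cell.  Pearson r/r2 are reported over survivors (needs >= 3).
    """
    excluded = {"year": 0, "bottom_flag": 0, "depth_mismatch": 0, "out_of_extent": 0, "no_data": 0}
    rows = []
    for cast in casts.itertuples(index=False):
        if not bathymetry.spec.contains(cast.x, cast.y):
            excluded["out_of_extent"] += 1
            continue
        if cast.year <= min_year:
            excluded["year"] += 1
            continue
        if not bool(cast.bottom_flag):
            excluded["bottom_flag"] += 1
            continue
        r, c = bathymetry.spec.assign_cell(cast.x, cast.y)
        bottom = bathymetry.data[r, c]
        if not np.isfinite(bottom):
            excluded["no_data"] += 1
            continue
        if abs(cast.sample_depth - bottom) > depth_tolerance * bottom:
            excluded["depth_mismatch"] += 1
            continue
        layer_value = layer.grid.data[r, c]
        if not np.isfinite(layer_value):
            excluded["no_data"] += 1
            continue
        rows.append((getattr(cast, layer.variable), layer_value))
    pairs = pd.DataFrame(rows, columns=["bottle", "layer"])
    if len(pairs) < 3 or pairs["bottle"].nunique() < 2 or pairs["layer"].nunique() < 2:
        return BottleValidation(layer.variable, len(pairs), None, None, excluded, pairs)
    r, _ = pearsonr(pairs["bottle"], pairs["layer"])
    return BottleValidation(layer.variable, len(pairs), float(r), float(r**2), excluded, pairs)


def correlation_prune(
    samples: pd.DataFrame,
    threshold: float = 0.7,
    keep_list: tuple[str, ...] = (),
) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of each variable pair whose |Pearson r| exceeds
    ``threshold``.

    The member not on ``keep_list`` is dropped; if both are droppable the
    later-listed column goes; if both are protected the pair is exempt.
    Returns the retained variable names (input order) and the full
    correlation matrix.
    """
    variables = list(samples.columns)
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    if len(samples) < 10:
        raise ValueError("need at least 10 sample points")
    unknown = set(keep_list) - set(variables)
    if unknown:
        raise ValueError(f"keep_list names unknown variables: {sorted(unknown)}")
    corr = samples.corr(method="pearson")
    retained = list(variables)
    while True:
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(retained):
            for b in retained[i + 1 :]:
                r = abs(corr.loc[a, b])
                if r > threshold and (a not in keep_list or b not in keep_list):
                    if best is None or r > best[0]:
                        best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        if a in keep_list:
            retained.remove(b)
        elif b in keep_list:
            retained.remove(a)
        else:
            retained.remove(b)  # later-listed of the pair
    return retained, corr
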