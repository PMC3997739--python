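"""Synthetic seascapes with known ground truth.

Every input the analysis pipeline consumes is emulated here: a
shelf-slope-canyon bathymetry with survey-track soundings, depth-binned
climatology volumes with coarse horizontal structure, presence records
sampled from a known suitability function (with optional clustered sampling
bias and injected contaminants carrying a hidden answer key), bottle casts,
sanctuary polygons, a slope-correlated substrate raster and vessel-tagged
trawl lines.  All generators are deterministic under the configured seed,
with one seeded stream per sub-task so adding a generator never perturbs the
others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .bathymetry_terrain import SoundingSet, horn_slope
from .grid import Grid, GridSpec
from .env_layers import DepthBinnedField
from .presence_qc import PresenceRecord

# sub-task ids for deterministic per-generator random streams
_T_BATHY, _T_SOUND, _T_CLIM, _T_PRES, _T_OVER, _T_BOTTLE = range(6)


def default_depth_levels(max_depth: float = 5500.0) -> tuple[float, ...]:
    """Standard climatology levels: 0,50,...,200 then 100 m steps to 2000,
    then 250 m steps down to ``max_depth``."""
    levels = [0.0, 50.0, 100.0, 150.0, 200.0]
    levels += [float(z) for z in range(300, 2001, 100)]
    levels += [float(z) for z in range(2250, int(max_depth) + 1, 250)]
    return tuple(levels)


def default_profiles() -> dict:
    """Depth profiles: temperature monotone decreasing, salinity monotone
    increasing, oxygen with a mid-depth minimum (an oxygen-minimum-zone
    analog)."""
    return {
        "temperature": lambda z: 2.0 + 8.0 * np.exp(-np.asarray(z, float) / 300.0),
        "salinity": lambda z: 33.0 + 1.5 * (1.0 - np.exp(-np.asarray(z, float) / 500.0)),
        "oxygen": lambda z: 6.0 - 5.2 * np.exp(-(((np.asarray(z, float) - 700.0) / 600.0) ** 2)),
    }


@dataclass
class SeascapeConfig:
    seed: int = 0
    grid_extent: tuple[int, int] = (100, 100)  # (rows, cols)
    cell_size: float = 500.0
    depth_levels: tuple[float, ...] = field(default_factory=default_depth_levels)
    max_depth: float = 3500.0
    n_presences: int = 300
    suitability_exponent: float = 6.0
    sampling_bias_strength: float = 0.0
    contaminant_rates: dict = field(
        default_factory=lambda: {
            "trawl": 0.05, "shallow": 0.05, "unknown_family": 0.05, "duplicate": 0.05
        }
    )
    true_weights: dict = field(
        default_factory=lambda: {"temperature": -1.2, "slope": 1.5, "depth": 1.0}
    )
    # bathymetry relief
    coverage_fraction: float = 0.35
    n_canyons: int = 4
    canyon_amplitude: float = 700.0
    n_seamounts: int = 6
    seamount_amplitude: float = 900.0
    noise_amplitude: float = 30.0
    sounding_noise: float = 5.0
    # climatology structure
    coarse_factor: int = 10
    horizontal_gradient: float = 0.15
    climatology_noise: float = 0.0
    # overlays
    n_bottle_casts: int = 250
    n_trawl_lines: int = 40
    n_vessels: int = 8
    substrate_factor: int = 2
    # taxonomy of clean records
    order: str = "Alcyonacea"
    suborder: str = "Alcyoniina"
    family: str = "Primnoidae"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage fraction must lie in (0, 1]")
        levels = np.asarray(self.depth_levels, dtype=float)
        if np.any(np.diff(levels) <= 0):
            raise ValueError("depth_levels must be strictly increasing")
        for key, rate in self.contaminant_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"contaminant rate {key}={rate} outside [0, 1]")
        if self.sampling_bias_strength < 0:
            raise ValueError("sampling_bias_strength must be >= 0")

    def rng(self, task: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, task])

    @property
    def grid_spec(self) -> GridSpec:
        rows, cols = self.grid_extent
        return GridSpec(x0=0.0, y0=0.0, cell_size=self.cell_size, rows=rows, cols=cols)


@dataclass
class SeascapeTruth:
    config: SeascapeConfig
    bathymetry: Grid
    soundings: SoundingSet
    true_layers: dict[str, Grid]
    true_suitability: Grid
    presences: list[PresenceRecord]
    bottle_casts: pd.DataFrame
    polygons: dict[str, BaseGeometry]
    bias_polygon: BaseGeometry | None
    substrate: Grid
    trawl_lines: list[tuple[np.ndarray, str]]


def _horizontal_field(spec: GridSpec, amplitude: float) -> np.ndarray:
    """Smooth cross-shore gradient shared by the true layers and the
    climatology volume (in [-amplitude, amplitude]; no along-shore trend, so
    alongshore partitions stay statistically exchangeable)."""
    x = (np.arange(spec.cols) + 0.5) / spec.cols
    X = np.tile(x, (spec.rows, 1))
    return amplitude * (2.0 * X - 1.0)


def make_bathymetry(config: SeascapeConfig) -> tuple[Grid, SoundingSet]:
    """Shelf ramp + Gaussian canyon incisions + Gaussian seamounts + smoothed
    noise, clipped to [10, max_depth]; soundings along survey-track rows
    covering ~``coverage_fraction`` of cells."""
    rows, cols = config.grid_extent
    if rows < 50 or cols < 50:
        raise ValueError("grid extent must be at least 50x50 cells")
    spec = config.grid_spec
    rng = config.rng(_T_BATHY)
    x_norm = (np.arange(cols) + 0.5) / cols
    y_norm = (np.arange(rows) + 0.5) / rows
    X, Y = np.meshgrid(x_norm, y_norm)
    depth = 10.0 + (config.max_depth - 10.0) * X  # linear shelf-to-abyss ramp
    # canyons and seamounts stratified alongshore so no latitude band is
    # systematically featureless
    for i in range(config.n_canyons):
        yc = (i + 0.5) / config.n_canyons + rng.uniform(-0.08, 0.08)
        width = rng.uniform(0.02, 0.06)
        depth += config.canyon_amplitude * np.exp(-(((Y - yc) / width) ** 2)) * X
    for i in range(config.n_seamounts):
        yc = (i + 0.5) / config.n_seamounts + rng.uniform(-0.06, 0.06)
        xc = rng.uniform(0.55, 0.95)
        radius = rng.uniform(0.03, 0.08)
        amp = config.seamount_amplitude * rng.uniform(0.5, 1.0)
        depth -= amp * np.exp(-(((X - xc) ** 2 + (Y - yc) ** 2) / radius**2))
    if config.noise_amplitude > 0:
        depth += config.noise_amplitude * gaussian_filter(
            rng.standard_normal((rows, cols)), sigma=2.0
        )
    depth = np.clip(depth, 10.0, config.max_depth)
    bathy = Grid(depth, spec, "bathymetry")

    srng = config.rng(_T_SOUND)
    stride = max(1, int(round(1.0 / config.coverage_fraction)))
    pts = []
    for r in range(0, rows, stride):  # survey tracks along grid rows
        for c in range(cols):
            jx, jy = srng.uniform(-0.3, 0.3, size=2) * config.cell_size
            x = spec.x0 + (c + 0.5) * config.cell_size + jx
            y = spec.y0 + (r + 0.5) * config.cell_size + jy
            z = depth[r, c] + (
                srng.normal(0.0, config.sounding_noise) if config.sounding_noise > 0 else 0.0
            )
            pts.append((x, y, max(z, 1.0)))
    return bathy, SoundingSet(np.asarray(pts))


def make_climatology(
    config: SeascapeConfig, profiles: dict | None = None
) -> dict[str, DepthBinnedField]:
    """One coarse horizontal grid per standard depth level and variable:
    profile(level) + horizontal gradient + seeded noise."""
    profiles = profiles if profiles is not None else default_profiles()
    rng = config.rng(_T_CLIM)
    spec = config.grid_spec
    factor = config.coarse_factor
    coarse = GridSpec(
        x0=spec.x0, y0=spec.y0, cell_size=spec.cell_size * factor,
        rows=max(1, spec.rows // factor), cols=max(1, spec.cols // factor),
    )
    levels = [z for z in config.depth_levels if z <= config.max_depth + 250]
    gradient = _horizontal_field(coarse, config.horizontal_gradient)
    out: dict[str, DepthBinnedField] = {}
    for variable, profile in profiles.items():
        grids = []
        for z in levels:
            base = float(profile(z))
            if not math.isfinite(base):
                raise ValueError(f"profile for {variable!r} undefined at {z} m")
            data = base + gradient
            if config.climatology_noise > 0:
                data = data + rng.normal(0.0, config.climatology_noise, size=data.shape)
            grids.append(Grid(data, coarse, f"{variable}_{z:g}m"))
        out[variable] = DepthBinnedField(variable=variable, levels=np.asarray(levels), grids=grids)
    return out


def _true_layers(config: SeascapeConfig, bathymetry: Grid) -> dict[str, Grid]:
    profiles = default_profiles()
    gradient = _horizontal_field(bathymetry.spec, config.horizontal_gradient)
    layers: dict[str, Grid] = {"depth": bathymetry.copy_with(bathymetry.data.copy(), "depth")}
    layers["slope"] = horn_slope(bathymetry, 2 * config.cell_size).slope
    for variable, profile in profiles.items():
        data = profile(bathymetry.data) + gradient
        data[~bathymetry.valid_mask] = np.nan
        layers[variable] = bathymetry.copy_with(data, variable)
    return layers


def _true_suitability(config: SeascapeConfig, layers: dict[str, Grid]) -> Grid:
    valid = np.ones(layers["depth"].data.shape, dtype=bool)
    for grid in layers.values():
        valid &= grid.valid_mask
    lin = np.zeros(valid.shape)
    for variable, weight in config.true_weights.items():
        v = layers[variable].data
        mu, sd = np.nanmean(v[valid]), np.nanstd(v[valid])
        lin = lin + weight * (v - mu) / (sd if sd > 0 else 1.0)
    s = expit(lin)
    s[~valid] = np.nan
    return layers["depth"].copy_with(s, "true_suitability")


def sample_presences(truth: "SeascapeTruth", config: SeascapeConfig) -> list[PresenceRecord]:
    """Clean records drawn with probability proportional to
    suitability**exponent (optionally boosted inside the bias polygon), plus
    contaminant records per ``contaminant_rates``, each carrying a hidden
    truth label."""
    if config.n_presences <= 0:
        raise ValueError("n_presences must be positive")
    rng = config.rng(_T_PRES)
    spec = truth.true_suitability.spec
    s = truth.true_suitability.data
    valid = np.isfinite(s)
    rr, cc = np.nonzero(valid)
    weights = s[valid] ** config.suitability_exponent
    if config.sampling_bias_strength > 0 and truth.bias_polygon is not None:
        minx, miny, maxx, maxy = truth.bias_polygon.bounds
        if maxx < spec.x0 or minx > spec.x0 + spec.width or maxy < spec.y0 or miny > spec.y0 + spec.height:
            raise ValueError("bias polygon outside grid extent")
        from shapely import contains_xy

        cx = spec.x0 + (cc + 0.5) * spec.cell_size
        cy = spec.y0 + (rr + 0.5) * spec.cell_size
        inside = contains_xy(truth.bias_polygon, cx, cy)
        weights = weights * (1.0 + config.sampling_bias_strength * inside)
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    p = weights / total
    n_cells = min(config.n_presences, int((p > 0).sum()))
    chosen = rng.choice(len(rr), size=n_cells, replace=False, p=p)
    gears = ("ROV", "submersible", "camera", "grab")
    records: list[PresenceRecord] = []
    for idx in chosen:
        r, c = rr[idx], cc[idx]
        jx, jy = rng.uniform(-0.3, 0.3, size=2) * spec.cell_size
        x = spec.x0 + (c + 0.5) * spec.cell_size + jx
        y = spec.y0 + (r + 0.5) * spec.cell_size + jy
        records.append(
            PresenceRecord(
                x=x, y=y,
                depth=max(float(truth.bathymetry.data[r, c] + rng.normal(0, 3.0)), 51.0),
                gear=str(rng.choice(gears)),
                order=config.order, suborder=config.suborder, family=config.family,
                source=f"SRC{rng.integers(5)}", truth_label="clean",
            )
        )
    clean = list(records)
    rates = config.contaminant_rates

    def _random_xy() -> tuple[float, float]:
        return (
            spec.x0 + rng.uniform(0, spec.width * 0.999999),
            spec.y0 + rng.uniform(0, spec.height * 0.999999),
        )

    for _ in range(int(round(rates.get("trawl", 0) * len(clean)))):
        base = clean[rng.integers(len(clean))]
        angle = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0, 2000.0)
        records.append(
            replace(
                base,
                x=float(np.clip(base.x + dist * np.cos(angle), spec.x0, spec.x0 + spec.width * 0.999999)),
                y=float(np.clip(base.y + dist * np.sin(angle), spec.y0, spec.y0 + spec.height * 0.999999)),
                gear="trawl", source="TRAWLDB", truth_label="contaminant_trawl",
            )
        )
    for _ in range(int(round(rates.get("shallow", 0) * len(clean)))):
        x, y = _random_xy()
        records.append(
            PresenceRecord(
                x=x, y=y, depth=float(rng.uniform(5.0, 49.9)), gear="camera",
                order=config.order, suborder=config.suborder, family=config.family,
                source="SHALLOWDB", truth_label="contaminant_shallow",
            )
        )
    for _ in range(int(round(rates.get("unknown_family", 0) * len(clean)))):
        x, y = _random_xy()
        records.append(
            PresenceRecord(
                x=x, y=y, depth=float(rng.uniform(60.0, config.max_depth)), gear="grab",
                order=config.order, suborder=config.suborder, family="unknown",
                source="LEGACYDB", truth_label="contaminant_unknown_family",
            )
        )
    for _ in range(int(round(rates.get("duplicate", 0) * len(clean)))):
        base = clean[rng.integers(len(clean))]
        r, c = spec.assign_cell(base.x, base.y)
        jx, jy = rng.uniform(-0.45, 0.45, size=2) * spec.cell_size
        records.append(
            replace(
                base,
                x=spec.x0 + (c + 0.5) * spec.cell_size + jx,
                y=spec.y0 + (r + 0.5) * spec.cell_size + jy,
                source="ZZDUPDB",  # sorts after clean sources so the original wins
                truth_label="contaminant_duplicate",
            )
        )
    return records


def make_overlays(
    config: SeascapeConfig, bathymetry: Grid, slope: Grid
) -> tuple[dict[str, BaseGeometry], Grid, list[tuple[np.ndarray, str]]]:
    """Sanctuary-analog polygons, a finer slope-correlated substrate raster,
    and vessel-tagged random trawl segments."""
    rng = config.rng(_T_OVER)
    spec = config.grid_spec
    w, h = spec.width, spec.height
    polygons: dict[str, BaseGeometry] = {
        "Sanctuary A": box(spec.x0 + 0.05 * w, spec.y0 + 0.55 * h, spec.x0 + 0.35 * w, spec.y0 + 0.9 * h),
        "Sanctuary B": box(spec.x0 + 0.4 * w, spec.y0 + 0.1 * h, spec.x0 + 0.7 * w, spec.y0 + 0.4 * h),
        "Sanctuary C": Point(spec.x0 + 0.75 * w, spec.y0 + 0.7 * h).buffer(0.12 * min(w, h)),
    }
    f = config.substrate_factor
    sub_spec = GridSpec(
        x0=spec.x0, y0=spec.y0, cell_size=spec.cell_size / f,
        rows=spec.rows * f, cols=spec.cols * f,
    )
    parent_slope = np.repeat(np.repeat(slope.data, f, axis=0), f, axis=1)
    p_hard = expit(-3.0 + 0.45 * np.nan_to_num(parent_slope, nan=0.0))
    u = rng.uniform(size=p_hard.shape)
    classes = np.where(u < p_hard, 2.0, np.where(u < p_hard + 0.25, 1.0, 0.0))
    parent_valid = np.repeat(np.repeat(bathymetry.valid_mask, f, axis=0), f, axis=1)
    classes[~parent_valid] = np.nan
    substrate = Grid(classes, sub_spec, "substrate")

    lines: list[tuple[np.ndarray, str]] = []
    for _ in range(config.n_trawl_lines):
        x0 = spec.x0 + rng.uniform(0.02, 0.45) * w  # trawling on the shelf side
        y0 = spec.y0 + rng.uniform(0.02, 0.98) * h
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(2_000.0, 10_000.0)
        x1 = float(np.clip(x0 + length * np.cos(angle), spec.x0, spec.x0 + w))
        y1 = float(np.clip(y0 + length * np.sin(angle), spec.y0, spec.y0 + h))
        lines.append((np.array([[x0, y0], [x1, y1]]), f"V{rng.integers(config.n_vessels)}"))
    return polygons, substrate, lines


def make_bottle_casts(
    config: SeascapeConfig, bathymetry: Grid, layers: dict[str, Grid]
) -> pd.DataFrame:
    """Bottle casts sampled near the seafloor at random valid cells: most are
    post-2001, bottom-flagged and within depth tolerance, the rest exercise
    the validation filters."""
    rng = config.rng(_T_BOTTLE)
    spec = bathymetry.spec
    rr, cc = np.nonzero(bathymetry.valid_mask)
    rows = []
    variables = [v for v in layers if v not in ("depth", "slope")]
    for _ in range(config.n_bottle_casts):
        i = rng.integers(len(rr))
        r, c = rr[i], cc[i]
        x = spec.x0 + (c + 0.5) * spec.cell_size
        y = spec.y0 + (r + 0.5) * spec.cell_size
        bottom = bathymetry.data[r, c]
        if rng.uniform() < 0.7:
            sample_depth = bottom * (1 + rng.uniform(-0.04, 0.04))
        else:
            sample_depth = bottom * (1 + rng.choice([-1, 1]) * rng.uniform(0.06, 0.3))
        row = {
            "x": x, "y": y,
            "sample_depth": max(float(sample_depth), 1.0),
            "year": int(rng.integers(1995, 2011)),
            "bottom_flag": bool(rng.uniform() < 0.8),
        }
        for v in variables:
            value = layers[v].data[r, c]
            row[v] = float(value + rng.normal(0, 0.01 * max(abs(value), 1.0)))
        rows.append(row)
    return pd.DataFrame(rows)


def generate(config: SeascapeConfig) -> SeascapeTruth:
    """Build a complete seascape: all generators wired together."""
    bathymetry, soundings = make_bathymetry(config)
    layers = _true_layers(config, bathymetry)
    suitability = _true_suitability(config, layers)
    polygons, substrate, trawl_lines = make_overlays(config, bathymetry, layers["slope"])
    bias_polygon = polygons["Sanctuary B"] if config.sampling_bias_strength > 0 else None
    truth = SeascapeTruth(
        config=config,
        bathymetry=bathymetry,
        soundings=soundings,
        true_layers=layers,
        true_suitability=suitability,
        presences=[],
        bottle_casts=make_bottle_casts(config, bathymetry, layers),
        polygons=polygons,
        bias_polygon=bias_polygon,
        substrate=substrate,
        trawl_lines=trawl_lines,
    )
    truth.presences = sample_presences(truth, config)
    return truth
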