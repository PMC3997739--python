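"""End-to-end orchestration: seascape inputs -> bathymetry -> seafloor
layers -> presence QC -> spatially cross-validated maxent models ->
consensus maps -> overlap reports."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import overlap_reports as rep
from .bathymetry_terrain import clean_soundings, grid_soundings, horn_slope
from .env_layers import correlation_prune, extrude_to_seafloor
from .grid import Grid, block_aggregate
from .presence_qc import build_taxon_sets, filter_records
from .spatial_cv import (
    ConsensusGrid,
    FoldResult,
    consensus_sum,
    partition_regions,
    run_spatial_cv,
    threshold_binary,
)
from .synthetic_seascape import SeascapeConfig, SeascapeTruth, generate, make_climatology

DEFAULT_VARIABLES = ("depth", "slope", "temperature", "salinity", "oxygen")
DEFAULT_KEEP_LIST = ("depth", "temperature")


@dataclass
class PipelineResult:
    truth: SeascapeTruth
    bathymetry: Grid
    layers: dict[str, Grid]
    variables: list[str]
    correlation_matrix: pd.DataFrame | None
    audit: pd.DataFrame
    taxon_label: str
    partition: object
    folds: list[FoldResult]
    consensus: dict[float, ConsensusGrid]
    cell_values: pd.DataFrame = field(repr=False, default=None)
    presence_values: pd.DataFrame = field(repr=False, default=None)
    valid_rc: np.ndarray = field(repr=False, default=None)
    background_idx: np.ndarray = field(repr=False, default=None)
    reports: dict = field(default_factory=dict)


def build_layers(config: SeascapeConfig, truth: SeascapeTruth) -> tuple[Grid, dict[str, Grid]]:
    """Stages 1-2: grid the soundings (with coarse infill) and construct the
    seafloor environmental layers from the depth-binned climatology."""
    spec = config.grid_spec
    cleaned = clean_soundings(truth.soundings, spec)
    infill = block_aggregate(truth.bathymetry, 5)  # coarse reference grid stand-in
    bathymetry, _ = grid_soundings(cleaned, spec, infill)
    layers: dict[str, Grid] = {
        "depth": bathymetry.copy_with(bathymetry.data.copy(), "depth"),
        "slope": horn_slope(bathymetry, 2 * config.cell_size).slope,
    }
    for variable, binned in make_climatology(config).items():
        layers[variable] = extrude_to_seafloor(binned, bathymetry).grid
    return bathymetry, layers


def run_pipeline(
    config: SeascapeConfig,
    n_background: int = 2_000,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
    keep_list: tuple[str, ...] = DEFAULT_KEEP_LIST,
    prune: bool = True,
    min_records: int = 50,
    reg_multiplier: float = 1.0,
    convergence: float = 1e-5,
    max_iterations: int = 500,
    bootstrap_reps: int = 100,
    with_jackknife: bool = False,
    with_reports: bool = False,
    partition_mode: str = "bands",
    seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis on a synthetic seascape.

    Background is a seeded uniform sample of valid cells (presence cells
    merged in); test background for every fold is the study-wide sample.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 99])
    truth = generate(config)
    spec = config.grid_spec
    bathymetry, layers = build_layers(config, truth)

    # presence QC
    retained, audit = filter_records(truth.presences, spec)
    taxon_sets = build_taxon_sets(retained, spec, min_records=min_records)
    modelable = [t for t in taxon_sets if t.modelable and t.label != "All taxa"]
    taxon = modelable[0] if modelable else taxon_sets[-1]

    # common valid mask and per-cell variable table
    valid = np.ones(spec.rows * spec.cols, dtype=bool).reshape(spec.rows, spec.cols)
    for var in variables:
        valid &= layers[var].valid_mask
    valid_rc = np.argwhere(valid)
    cell_values = pd.DataFrame({var: layers[var].data[valid] for var in variables})

    corr = None
    use_vars = list(variables)
    if prune and len(variables) >= 2:
        sample_idx = rng.choice(len(cell_values), size=min(1000, len(cell_values)), replace=False)
        use_vars, corr = correlation_prune(
            cell_values.iloc[sample_idx],
            threshold=0.7,
            keep_list=tuple(k for k in keep_list if k in variables),
        )
        cell_values = cell_values[use_vars]

    # presence values at their cells (records on no-data cells dropped)
    rc_to_row = {tuple(rc): i for i, rc in enumerate(valid_rc)}
    pres_rows, kept_records = [], []
    for record in taxon.records:
        rc = spec.assign_cell(record.x, record.y)
        if rc in rc_to_row:
            pres_rows.append(rc_to_row[rc])
            kept_records.append(record)
    presence_values = cell_values.iloc[pres_rows].reset_index(drop=True)
    presence_xy = np.array([[r.x, r.y] for r in kept_records])

    # study-wide background sample, presences merged in
    bg = rng.choice(len(cell_values), size=min(n_background, len(cell_values)), replace=False)
    background_idx = np.union1d(bg, np.asarray(pres_rows))

    partition = partition_regions(presence_xy, mode=partition_mode)
    folds = run_spatial_cv(
        taxon, cell_values, presence_values, partition, bathymetry, valid_rc,
        background_idx=background_idx, reg_multiplier=reg_multiplier,
        convergence=convergence, max_iterations=max_iterations,
        bootstrap_reps=bootstrap_reps, seed=seed, with_jackknife=with_jackknife,
    )

    consensus: dict[float, ConsensusGrid] = {}
    retained_folds = [f for f in folds if f.retained]
    for cutoff in (0.5, 0.75):
        if retained_folds:
            binaries = [threshold_binary(f.hsi, cutoff) for f in retained_folds]
            consensus[cutoff] = consensus_sum(binaries, cutoff, taxon.label)

    result = PipelineResult(
        truth=truth, bathymetry=bathymetry, layers=layers, variables=use_vars,
        correlation_matrix=corr, audit=audit, taxon_label=taxon.label,
        partition=partition, folds=folds, consensus=consensus,
        cell_values=cell_values, presence_values=presence_values,
        valid_rc=valid_rc, background_idx=background_idx,
    )
    if with_reports and consensus:
        main = consensus[0.5]
        intensity = rep.trawl_line_density(truth.trawl_lines, spec)
        bins = np.array([0.0, 1e-9, 0.05, 0.1, 0.2, 0.5, 1.0, np.inf])
        result.reports = {
            "zonal": rep.zonal_area(main, truth.polygons),
            "substrate": rep.substrate_cross_tab(main, truth.substrate),
            "intensity": intensity,
            "intensity_by_class": rep.intensity_by_class(main, intensity, bins),
            "niche": rep.niche_summary(presence_values)[0],
        }
    return result
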