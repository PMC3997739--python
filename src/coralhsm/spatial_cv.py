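"""Spatially partitioned cross-validation, presence-background AUC, threshold
statistics, and thresholded consensus mapping.

Presences are split into four geographic regions (supplied polygons, or
quadrants at the presence median easting/northing).  Each fold trains on
three regions, scores the held-out region's presences against the study-wide
background, and is retained only if its test AUC exceeds 0.7.  Retained
folds' suitability surfaces are binarised at a strict cutoff (0.5 or 0.75)
and summed into a consensus grid valued 0..K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from shapely.geometry.base import BaseGeometry

from .grid import Grid
from .presence_qc import TaxonSet

AUC_RETENTION = 0.7


def is_retained(auc: float) -> bool:
    """Fold retention rule: strictly greater than the 0.7 bar."""
    return auc > AUC_RETENTION


@dataclass
class RegionPartition:
    """Assignment of each presence to exactly one of four regions (0..3)."""

    assignment: np.ndarray
    boundaries: dict[str, BaseGeometry] | None = None
    split_x: float | None = None
    split_y: float | None = None
    band_breaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=4)

    def assign_points(self, xy: np.ndarray) -> np.ndarray:
        """Assign arbitrary points with the same rule used for presences."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        if self.boundaries is not None:
            return _polygon_assign(xy, self.boundaries)
        if self.band_breaks is not None:
            return _band_assign(xy, self.band_breaks)
        return _quadrant_assign(xy, self.split_x, self.split_y)


def _quadrant_assign(xy: np.ndarray, split_x: float, split_y: float) -> np.ndarray:
    # ties on a split line go to the lower-index region (strict >)
    return (xy[:, 0] > split_x).astype(int) + 2 * (xy[:, 1] > split_y).astype(int)


def _band_assign(xy: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    # alongshore latitude bands; a point on a break joins the lower band
    return np.searchsorted(breaks, xy[:, 1], side="left").clip(0, 3)


def _polygon_assign(xy: np.ndarray, boundaries: dict[str, BaseGeometry]) -> np.ndarray:
    from shapely import contains_xy, intersects_xy

    out = np.full(len(xy), -1, dtype=int)
    # strict interior first; then boundary touches, lowest region index wins
    for idx, geom in enumerate(boundaries.values()):
        sel = (out == -1) & contains_xy(geom, xy[:, 0], xy[:, 1])
        out[sel] = idx
    for idx, geom in enumerate(boundaries.values()):
        sel = (out == -1) & intersects_xy(geom, xy[:, 0], xy[:, 1])
        out[sel] = idx
    # points outside every polygon: nearest region
    missing = np.flatnonzero(out == -1)
    if len(missing):
        from shapely.geometry import Point

        geoms = list(boundaries.values())
        for i in missing:
            out[i] = int(np.argmin([g.distance(Point(xy[i])) for g in geoms]))
    return out


def partition_regions(
    presence_xy: np.ndarray,
    boundaries: dict[str, BaseGeometry] | None = None,
    mode: str = "quadrant",
) -> RegionPartition:
    """Partition presences into four regions.

    With polygon boundaries: point-in-polygon (edge/outside points fall to
    the nearest region).  Without: ``mode="quadrant"`` splits at the median
    easting and northing of the presences (split-line ties to the
    lower-index region); ``mode="bands"`` cuts four alongshore latitude
    bands at the presence northing quartiles, so each region spans the full
    coast-to-abyss gradient.
    """
    xy = np.asarray(presence_xy, dtype=float).reshape(-1, 2)
    if len(xy) < 4:
        raise ValueError("need at least four presences to partition")
    if boundaries is not None:
        if len(boundaries) != 4:
            raise ValueError("exactly four region polygons required")
        return RegionPartition(_polygon_assign(xy, boundaries), boundaries=boundaries)
    if mode == "bands":
        breaks = np.quantile(xy[:, 1], [0.25, 0.5, 0.75])
        return RegionPartition(_band_assign(xy, breaks), band_breaks=breaks)
    if mode != "quadrant":
        raise ValueError(f"unknown partition mode {mode!r}")
    split_x = float(np.median(xy[:, 0]))
    split_y = float(np.median(xy[:, 1]))
    return RegionPartition(
        _quadrant_assign(xy, split_x, split_y), split_x=split_x, split_y=split_y
    )


def auc_presence_background(presence_scores, background_scores) -> float:
    """Probability that a presence outranks a random background site, ties
    credited one half (the normalised Mann-Whitney statistic)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("presence and background score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
    return float(u / (len(p) * len(b)))


def auc_significance(presence_scores, background_scores) -> float:
    """Two-sided rank-sum p-value (normal approximation, tie-corrected) for
    the hypothesis that presences rank no differently than background."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) < 5 or len(b) < 5:
        raise ValueError("need at least 5 scores per group")
    n_p, n_b = len(p), len(b)
    combined = np.concatenate([p, b])
    ranks = rankdata(combined)
    u = ranks[:n_p].sum() - n_p * (n_p + 1) / 2
    n = n_p + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n_p * n_b / 12 * (n + 1 - tie_term)
    if var_u <= 0:
        return 1.0
    z = (abs(u - n_p * n_b / 2) - 0.5) / np.sqrt(var_u)  # continuity corrected
    return float(2 * norm.sf(max(z, 0.0)))


def p10_training_presence(training_scores) -> float:
    """Nearest-rank 10th percentile of training presence scores."""
    s = np.sort(np.asarray(training_scores, dtype=float))
    if len(s) == 0:
        raise ValueError("empty training scores")
    idx = max(int(np.ceil(0.1 * len(s))) - 1, 0)
    return float(s[idx])


def max_sens_plus_spec(test_scores, background_scores) -> tuple[float, float]:
    """Threshold maximising sensitivity(test) + specificity(background), with
    suitability declared by a strict ``score > threshold``.

    Returns (threshold, sens+spec at optimum); the threshold is the midpoint
    of the optimal interval between adjacent candidate scores.
    """
    t = np.asarray(test_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    cand = np.unique(np.concatenate([t, b]))
    best_obj, best_k = -np.inf, 0
    for k, thr in enumerate(cand):
        obj = (t > thr).mean() + (b <= thr).mean()
        if obj > best_obj:
            best_obj, best_k = obj, k
    if best_k + 1 < len(cand):
        thr = (cand[best_k] + cand[best_k + 1]) / 2
    else:
        thr = cand[best_k]
    return float(thr), float(best_obj)


@dataclass
class FoldResult:
    fold: int
    model: object
    auc: float
    auc_sd: float
    p_value: float
    p10: float
    max_ss_threshold: float
    retained: bool
    n_train: int
    n_test: int
    hsi: Grid | None = None
    jackknife: pd.DataFrame | None = field(default=None, repr=False)


def bootstrap_auc_sd(
    presence_scores, background_scores, n_reps: int = 100, seed: int = 0
) -> float:
    """Standard deviation of the test AUC under bootstrap resampling of test
    presences (background held fixed)."""
    rng = np.random.default_rng(seed)
    p = np.asarray(presence_scores, dtype=float)
    aucs = [
        auc_presence_background(rng.choice(p, size=len(p), replace=True), background_scores)
        for _ in range(n_reps)
    ]
    return float(np.std(aucs))


def run_spatial_cv(
    taxon: TaxonSet,
    cell_values: pd.DataFrame,
    presence_values: pd.DataFrame,
    partition: RegionPartition,
    grid_template: Grid,
    valid_rc: np.ndarray,
    background_idx: np.ndarray | None = None,
    reg_multiplier: float = 1.0,
    convergence: float = 1e-5,
    max_iterations: int = 500,
    bootstrap_reps: int = 100,
    seed: int = 0,
    with_jackknife: bool = False,
) -> list[FoldResult]:
    """Run the four-region spatial cross-validation for one taxon.

    ``cell_values`` holds environmental values for every valid cell (the
    rows scored into HSI surfaces), ``valid_rc`` their (row, col) in
    ``grid_template`` and ``background_idx`` the rows used as the
    study-wide background sample (all rows when omitted).
    ``presence_values`` holds values per presence, aligned with
    ``partition.assignment``.  Folds with empty test sets are skipped; fewer
    than two usable folds is an error.
    """
    from . import maxent_sdm as mx

    assignment = partition.assignment
    if len(assignment) != len(presence_values):
        raise ValueError("partition does not match presence table")
    if background_idx is None:
        background_idx = np.arange(len(cell_values))
    background_values = cell_values.iloc[background_idx]
    results: list[FoldResult] = []
    for region in range(4):
        test_mask = assignment == region
        train_mask = ~test_mask
        if test_mask.sum() == 0 or train_mask.sum() < 2:
            continue
        train = presence_values[train_mask]
        test = presence_values[test_mask]
        specs = mx.build_features(background_values, m=len(train))
        B = mx.featurize(specs, background_values)
        P = mx.featurize(specs, train)
        model = mx.fit_maxent(
            P, B, features=specs, reg_multiplier=reg_multiplier,
            convergence=convergence, max_iterations=max_iterations, seed=seed,
        )
        bg_hsi = mx.logistic_output(model, B)
        train_hsi = mx.logistic_output(model, P)
        test_hsi = mx.logistic_output(model, mx.featurize(specs, test))
        auc = auc_presence_background(test_hsi, bg_hsi)
        auc_sd = bootstrap_auc_sd(test_hsi, bg_hsi, bootstrap_reps, seed=seed + region)
        try:
            p_value = auc_significance(test_hsi, bg_hsi)
        except ValueError:
            p_value = float("nan")
        thr, _ = max_sens_plus_spec(test_hsi, bg_hsi)
        all_hsi = mx.logistic_output(model, mx.featurize(specs, cell_values))
        hsi_grid = Grid.full(grid_template.spec, np.nan, f"hsi_fold{region + 1}")
        hsi_grid.data[valid_rc[:, 0], valid_rc[:, 1]] = all_hsi
        jk = None
        if with_jackknife:
            jk = mx.jackknife_importance(
                train, background_values, test,
                reg_multiplier=reg_multiplier, convergence=convergence,
                max_iterations=max_iterations,
            )
        results.append(
            FoldResult(
                fold=region + 1,
                model=model,
                auc=auc,
                auc_sd=auc_sd,
                p_value=p_value,
                p10=p10_training_presence(train_hsi),
                max_ss_threshold=thr,
                retained=is_retained(auc),
                n_train=int(train_mask.sum()),
                n_test=int(test_mask.sum()),
                hsi=hsi_grid,
                jackknife=jk,
            )
        )
    if len(results) < 2:
        raise RuntimeError(f"taxon {taxon.label!r}: fewer than two usable folds")
    return results


def threshold_binary(hsi: Grid, cutoff: float) -> Grid:
    """Binarise an HSI grid with a strict ``> cutoff`` rule; no-data
    propagates."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    data = np.where(hsi.valid_mask, (hsi.data > cutoff).astype(float), np.nan)
    return hsi.copy_with(data, f"{hsi.name}_gt{cutoff}")


@dataclass
class ConsensusGrid:
    grid: Grid
    k: int
    threshold: float
    taxon: str = ""


def consensus_sum(
    binaries: list[Grid], threshold: float, taxon: str = ""
) -> ConsensusGrid:
    """Cellwise sum of the retained folds' binary grids (values 0..K)."""
    if not binaries:
        raise ValueError("need at least one retained fold")
    spec = binaries[0].spec
    if any(b.spec != spec for b in binaries):
        raise ValueError("binary grids have mismatched geometry")
    stack = np.stack([b.data for b in binaries])
    valid = np.all(np.isfinite(stack), axis=0)
    total = np.where(valid, stack.sum(axis=0), np.nan)
    return ConsensusGrid(
        Grid(total, spec, f"consensus_{taxon}_{threshold}"), k=len(binaries),
        threshold=threshold, taxon=taxon,
    )


def fold_report(results: list[FoldResult]) -> pd.DataFrame:
    """Per-fold validation statistics, one column per fold."""
    rows = {
        "Test AUC": [r.auc for r in results],
        "Test AUC standard deviation": [r.auc_sd for r in results],
        "p-value": [r.p_value for r in results],
        "10th percentile training presence": [r.p10 for r in results],
        "Maximum test sensitivity plus specificity": [r.max_ss_threshold for r in results],
        "Retained": [r.retained for r in results],
        "n train": [r.n_train for r in results],
        "n test": [r.n_test for r in results],
    }
    return pd.DataFrame(rows, index=[f"fold {r.fold}" for r in results]).T
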