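"""Quality control of coral presence records.

Four elimination rules, applied in order so every record carries a single
primary removal reason: (1) trawl-caught records, (2) records shallower than
50 m, (3) records with unknown family-level taxonomy, (4) spatial duplicates
of the same taxon within one analysis cell.  Survivors are binned to cells
per taxon (order or suborder), and taxa with too few records are flagged as
unmodelable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import GridSpec

GEAR_TYPES = ("trawl", "ROV", "submersible", "camera", "grab", "other")

QC_RETAINED = "retained"
QC_TRAWL = "removed_trawl"
QC_SHALLOW = "removed_shallow"
QC_TAXONOMY = "removed_taxonomy"
QC_DUPLICATE = "removed_duplicate"
QC_OUT_OF_EXTENT = "out_of_extent"


@dataclass
class PresenceRecord:
    x: float
    y: float
    depth: float
    gear: str
    order: str
    suborder: str | None = None
    family: str = "unknown"
    source: str = ""
    qc_status: str | None = None
    truth_label: str | None = None  # synthetic answer key; ignored by analysis

    @property
    def taxon(self) -> str:
        """Modelling taxon: suborder when known, else order."""
        return self.suborder if self.suborder else self.order


@dataclass
class TaxonSet:
    label: str
    records: list[PresenceRecord]
    cells: dict[tuple[int, int], int] = field(default_factory=dict)
    modelable: bool = True

    @property
    def n(self) -> int:
        return len(self.records)

    def presence_xy(self) -> np.ndarray:
        return np.array([[r.x, r.y] for r in self.records], dtype=float).reshape(-1, 2)


def assign_cell(x: float, y: float, grid_spec: GridSpec) -> tuple[int, int]:
    """Half-open cell assignment, shared with the gridding stage."""
    return grid_spec.assign_cell(x, y)


def filter_records(
    records: list[PresenceRecord],
    grid_spec: GridSpec,
    min_depth: float = 50.0,
) -> tuple[list[PresenceRecord], pd.DataFrame]:
    """Apply the four elimination rules in order; return retained records and
    an audit table of counts per rule and taxon.

    Records outside the grid extent are flagged separately and take no part
    in cell assignment.  Duplicate resolution keeps the first record per
    (taxon, cell) after a deterministic sort by (source, x, y, depth).
    """
    statused: list[PresenceRecord] = []
    survivors: list[PresenceRecord] = []
    for rec in records:
        if not grid_spec.contains(rec.x, rec.y):
            statused.append(replace(rec, qc_status=QC_OUT_OF_EXTENT))
        elif rec.gear == "trawl":
            statused.append(replace(rec, qc_status=QC_TRAWL))
        elif rec.depth < min_depth:
            statused.append(replace(rec, qc_status=QC_SHALLOW))
        elif rec.family == "unknown":
            statused.append(replace(rec, qc_status=QC_TAXONOMY))
        else:
            survivors.append(rec)
    survivors.sort(key=lambda r: (r.source, r.x, r.y, r.depth))
    seen: set[tuple[str, int, int]] = set()
    retained: list[PresenceRecord] = []
    for rec in survivors:
        key = (rec.taxon, *assign_cell(rec.x, rec.y, grid_spec))
        if key in seen:
            statused.append(replace(rec, qc_status=QC_DUPLICATE))
        else:
            seen.add(key)
            rec = replace(rec, qc_status=QC_RETAINED)
            retained.append(rec)
            statused.append(rec)
    rows = [
        {"taxon": r.taxon, "status": r.qc_status} for r in statused
    ]
    audit = (
        pd.DataFrame(rows, columns=["taxon", "status"])
        .groupby(["taxon", "status"])
        .size()
        .unstack(fill_value=0)
        .reindex(
            columns=[QC_RETAINED, QC_TRAWL, QC_SHALLOW, QC_TAXONOMY, QC_DUPLICATE, QC_OUT_OF_EXTENT],
            fill_value=0,
        )
    )
    return retained, audit


def build_taxon_sets(
    retained: list[PresenceRecord],
    grid_spec: GridSpec,
    min_records: int = 50,
    all_label: str = "All taxa",
) -> list[TaxonSet]:
    """Group retained records into one TaxonSet per taxon plus an all-taxa
    union; sets below ``min_records`` are flagged unmodelable."""
    by_taxon: dict[str, list[PresenceRecord]] = {}
    for rec in retained:
        by_taxon.setdefault(rec.taxon, []).append(rec)
    sets = []
    for label in sorted(by_taxon):
        recs = by_taxon[label]
        cells = {assign_cell(r.x, r.y, grid_spec): 1 for r in recs}
        sets.append(TaxonSet(label, recs, cells, modelable=len(recs) >= min_records))
    union_cells: dict[tuple[int, int], int] = {}
    for r in retained:
        union_cells[assign_cell(r.x, r.y, grid_spec)] = 1
    sets.append(
        TaxonSet(all_label, list(retained), union_cells, modelable=len(retained) >= min_records)
    )
    return sets


def records_to_frame(records: list[PresenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x": r.x, "y": r.y, "depth": r.depth, "gear": r.gear,
                "order": r.order, "suborder": r.suborder or "",
                "family": r.family, "source": r.source,
                "qc_status": r.qc_status or "", "truth_label": r.truth_label or "",
            }
            for r in records
        ]
    )


def frame_to_records(frame: pd.DataFrame) -> list[PresenceRecord]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            PresenceRecord(
                x=float(row.x), y=float(row.y), depth=float(row.depth),
                gear=str(row.gear), order=str(row.order),
                suborder=str(getattr(row, "suborder", "")) or None,
                family=str(getattr(row, "family", "unknown")) or "unknown",
                source=str(getattr(row, "source", "")),
                truth_label=str(getattr(row, "truth_label", "")) or None,
            )
        )
    return out
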