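"""Readers and writers for the plain-text exchange formats used throughout:
XYZ soundings, GeoJSON vectors, and CSV record tables."""

from __future__ import annotations

import json
import re

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


def read_xyz(path) -> np.ndarray:
    """Read whitespace- or comma-delimited x y z triples into an (n, 3) array."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 3:
                raise ValueError(f"malformed XYZ line: {line!r}")
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def write_xyz(path, points: np.ndarray) -> None:
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.6f")


def read_geojson(path) -> dict[str, dict]:
    """Read a GeoJSON FeatureCollection into {name: {"geometry", "properties"}}.

    Features without a ``name`` property are keyed ``feature_<i>``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    out: dict[str, dict] = {}
    for i, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        name = props.get("name", f"feature_{i}")
        out[name] = {"geometry": shape(feature["geometry"]), "properties": props}
    return out


def write_geojson(path, features: dict[str, BaseGeometry] | list[tuple[BaseGeometry, dict]]) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection.

    Accepts either ``{name: geometry}`` or ``[(geometry, properties), ...]``.
    """
    if isinstance(features, dict):
        items = [(geom, {"name": name}) for name, geom in features.items()]
    else:
        items = list(features)
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in items
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)
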