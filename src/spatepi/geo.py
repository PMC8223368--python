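"""Reading and writing cluster point layers (CSV and GeoJSON).

GeoJSON is always WGS84 with [lon, lat] coordinate order; every non-geometry
column becomes a feature property.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def _py(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def points_to_geojson(df: pd.DataFrame, lon: str = "lon", lat: str = "lat",
                      properties=None) -> dict:
    """Point FeatureCollection from a table with lon/lat columns."""
    if properties is None:
        properties = [c for c in df.columns if c not in (lon, lat)]
    features = []
    for _, row in df.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row[lon]), float(row[lat])]},
            "properties": {c: _py(row[c]) for c in properties},
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path):
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def geojson_to_points(obj: dict) -> pd.DataFrame:
    """Flatten a Point FeatureCollection back into a table with lon/lat."""
    rows = []
    for feat in obj["features"]:
        if feat["geometry"]["type"] != "Point":
            raise ValueError("only Point geometries supported")
        lon, lat = feat["geometry"]["coordinates"][:2]
        rows.append({"lon": float(lon), "lat": float(lat),
                     **feat.get("properties", {})})
    return pd.DataFrame(rows)


def read_locations(path) -> pd.DataFrame:
    """Cluster locations from CSV (cluster_id, lon, lat[, urban]) or GeoJSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"locations file not found: {path}")
    if path.suffix.lower() in (".geojson", ".json"):
        df = geojson_to_points(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    for col in ("cluster_id", "lon", "lat"):
        if col not in df.columns:
            raise ValueError(f"locations file {path} lacks column {col!r}")
    return df
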