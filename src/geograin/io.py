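"""File I/O: survey CSV, long-format map CSV, GeoJSON polygons.

Canonical formats: surveys and maps are plain CSV with (lon, lat) columns
in WGS84 decimal degrees; administrative units are GeoJSON polygons.
Numeric round-trips are lossless at 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

SURVEY_REQUIRED = ("site_id", "lon", "lat", "value")


def read_survey_csv(path) -> pd.DataFrame:
    """Read a survey table, validating schema and coordinates.

    Requires columns ``site_id, lon, lat, value``; rows with out-of-range
    coordinates or non-finite values are rejected with their line numbers
    (header = line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path} is missing required columns: {missing}")
    bad = []
    for i, row in df.iterrows():
        line = i + 2  # header on line 1
        if not (-180.0 <= row["lon"] <= 180.0):
            bad.append((line, f"lon={row['lon']!r} outside [-180, 180]"))
        if not (-90.0 <= row["lat"] <= 90.0):
            bad.append((line, f"lat={row['lat']!r} outside [-90, 90]"))
        v = row["value"]
        if pd.isna(v) or v in (float("inf"), float("-inf")):
            bad.append((line, f"value={v!r} not finite"))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:20])
        raise ValueError(f"malformed rows in {path}: {detail}")
    return df


def write_grid_csv(path, frame: pd.DataFrame) -> None:
    """Write a long-format map table at 12 significant digits."""
    frame.to_csv(path, index=False, float_format="%.12g")


def write_survey_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def read_grid_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("lon", "lat"):
        if c not in df.columns:
            raise ValueError(f"grid file {path} is missing column {c!r}")
    return df


def read_polygons_geojson(path):
    """Read GeoJSON features as (properties, shapely geometry) pairs.

    Accepts a FeatureCollection, a single Feature, or a bare geometry.
    Polygon holes are preserved and respected by interior discretization.
    """
    with open(path) as fh:
        gj = json.load(fh)
    t = gj.get("type")
    if t == "FeatureCollection":
        return [(f.get("properties") or {}, shape(f["geometry"]))
                for f in gj["features"]]
    if t == "Feature":
        return [(gj.get("properties") or {}, shape(gj["geometry"]))]
    return [({}, shape(gj))]


def write_polygons_geojson(path, features) -> None:
    """Write (properties, geometry) pairs as a GeoJSON FeatureCollection."""
    fc = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "properties": props,
                        "geometry": mapping(geom)} for props, geom in features]}
    Path(path).write_text(json.dumps(fc))
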