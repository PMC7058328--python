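"""Readers and writers for the vector and tabular artifacts of a region run.

GeoJSON is used for patch polygons and the river polyline (planar
coordinates in meters, not longitude/latitude — the files carry a
``crs_units`` hint in their top-level properties). CSV is used for all
tables, YAML for configuration echoes.
"""
from __future__ import annotations

import json
from pathlib import Path

import yaml
from shapely.geometry import LineString, Polygon, mapping, shape

__all__ = [
    "write_patches_geojson",
    "read_patches_geojson",
    "write_line_geojson",
    "read_line_geojson",
    "write_config_echo",
    "read_config",
]


def write_patches_geojson(patches: dict[object, Polygon], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"patch_id": str(pid)},
            "geometry": mapping(poly),
        }
        for pid, poly in patches.items()
    ]
    doc = {"type": "FeatureCollection", "crs_units": "meters", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_patches_geojson(path: str | Path) -> dict[str, Polygon]:
    doc = json.loads(Path(path).read_text())
    out: dict[str, Polygon] = {}
    for feat in doc["features"]:
        out[feat["properties"]["patch_id"]] = shape(feat["geometry"])
    return out


def write_line_geojson(line: LineString, path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "crs_units": "meters",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(line)}
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_line_geojson(path: str | Path) -> LineString:
    doc = json.loads(Path(path).read_text())
    return shape(doc["features"][0]["geometry"])


def write_config_echo(config: dict, path: str | Path) -> None:
    """Echo the effective configuration for provenance (stable key order)."""
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
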