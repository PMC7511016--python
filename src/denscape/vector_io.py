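"""GeoJSON-backed vector I/O for routes, heliports and permit polygons.

Geometries live in the same projected planar metre coordinate system as the
rasters; files are plain GeoJSON written with the standard library.
"""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import mapping, shape


def write_geojson(geoms, path: str | Path, properties=None) -> None:
    """Write one geometry or a list of geometries as a FeatureCollection."""
    if not isinstance(geoms, (list, tuple)):
        geoms = [geoms]
    properties = properties or [{} for _ in geoms]
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geoms, properties)
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list:
    """Read all feature geometries from a GeoJSON file."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in doc["features"]]
    if doc.get("type") == "Feature":
        return [shape(doc["geometry"])]
    return [shape(doc)]
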