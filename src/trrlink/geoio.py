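"""GeoJSON (RFC 7946) and CSV serialization.

Each polygon layer is one FeatureCollection; every feature must carry an
``id`` property. Output is deterministic (sorted keys, stable float repr)
so identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


class Layer(dict):
    """Ordered id -> (geometry, properties) mapping for one polygon layer."""

    def __init__(self) -> None:
        super().__init__()
        self.properties: dict[str, dict[str, Any]] = {}

    def add(self, ident: str, geom: BaseGeometry, **props: Any) -> None:
        if ident in self:
            raise ValueError(f"duplicate feature id {ident!r}")
        self[ident] = geom
        self.properties[ident] = dict(props)


def layer_to_geojson(layer: Layer) -> dict:
    features = []
    for ident, geom in layer.items():
        props = {"id": ident, **layer.properties.get(ident, {})}
        features.append(
            {"type": "Feature", "id": ident, "properties": props,
             "geometry": mapping(geom)}
        )
    return {"type": "FeatureCollection", "features": features}


def write_layer(layer: Layer, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(layer_to_geojson(layer), sort_keys=True, separators=(",", ":"))
        + "\n"
    )


def read_layer(path: str | Path) -> Layer:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    layer = Layer()
    for feat in doc["features"]:
        props = dict(feat.get("properties") or {})
        ident = props.pop("id", feat.get("id"))
        if ident is None:
            raise ValueError(f"{path}: feature without mandatory 'id' property")
        layer.add(str(ident), shape(feat["geometry"]), **props)
    return layer


def write_json(obj: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")
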