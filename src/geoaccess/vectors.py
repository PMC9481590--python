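"""GeoJSON vector reading and writing.

Features are shapely geometries plus an attribute mapping.  GeoJSON itself is
CRS-less (RFC 7946 mandates WGS84), but this pipeline works on a projected
metric plane, so files written here carry a non-standard top-level ``crs_id``
member; readers fall back to ``local:metric`` when it is absent so hand-made
fixtures stay terse.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator

import shapely
from shapely.geometry import mapping, shape

__all__ = ["Feature", "FeatureCollection", "read_vectors", "write_vectors", "GeometryKindError"]

log = logging.getLogger(__name__)

_KIND_TYPES = {
    "point": {"Point", "MultiPoint"},
    "line": {"LineString", "MultiLineString"},
    "polygon": {"Polygon", "MultiPolygon"},
}


class GeometryKindError(ValueError):
    """A feature's geometry type does not match the requested kind."""


@dataclass
class Feature:
    geometry: shapely.Geometry
    attrs: dict[str, Any] = field(default_factory=dict)


@dataclass
class FeatureCollection:
    features: list[Feature]
    crs_id: str = "local:metric"

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def geometries(self) -> list[shapely.Geometry]:
        return [f.geometry for f in self.features]


def read_vectors(path, geometry_kind: str) -> FeatureCollection:
    """Read a GeoJSON file, enforcing a homogeneous geometry kind.

    Parameters
    ----------
    geometry_kind
        One of ``point``, ``line``, ``polygon``.  A file whose features are of
        another kind raises :class:`GeometryKindError` — reading polygons "as
        lines" would silently drop topology.
    """
    if geometry_kind not in _KIND_TYPES:
        raise ValueError(f"geometry_kind must be one of {sorted(_KIND_TYPES)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vector file not found: {path}")
    doc = json.loads(path.read_text())
    if doc.get("type") == "Feature":
        raw_features = [doc]
    elif doc.get("type") == "FeatureCollection":
        raw_features = doc.get("features", [])
    else:
        raise ValueError(f"{path}: not a GeoJSON Feature or FeatureCollection")

    allowed = _KIND_TYPES[geometry_kind]
    features = []
    for raw in raw_features:
        geom = shape(raw["geometry"])
        if geom.geom_type not in allowed:
            raise GeometryKindError(
                f"{path}: expected {geometry_kind} features, found {geom.geom_type}"
            )
        features.append(Feature(geometry=geom, attrs=dict(raw.get("properties") or {})))
    if not features:
        log.warning("%s: empty %s layer", path, geometry_kind)
    return FeatureCollection(features=features, crs_id=doc.get("crs_id", "local:metric"))


def write_vectors(path, features: Iterable[Feature], crs_id: str = "local:metric") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "type": "FeatureCollection",
        "crs_id": crs_id,
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": f.attrs,
            }
            for f in features
        ],
    }
    path.write_text(json.dumps(doc))
    return path
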