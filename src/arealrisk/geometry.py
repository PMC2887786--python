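"""Polygon layer container and GeoJSON round-trip.

Study regions are plain planar polygon tessellations (no CRS handling):
each area has a unique string ID stored in the GeoJSON property
``area_id``, alongside any extra per-area attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry


@dataclass
class PolygonLayer:
    """Ordered collection of (area_id, polygon) pairs with optional attributes."""

    ids: list[str]
    geoms: list[BaseGeometry]
    properties: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.geoms):
            raise ValueError("ids and geoms must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("area IDs must be unique")
        if not self.properties:
            self.properties = [{} for _ in self.ids]
        if len(self.properties) != len(self.ids):
            raise ValueError("properties must align with ids")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, BaseGeometry]]:
        return iter(zip(self.ids, self.geoms))

    def geom_of(self, area_id: str) -> BaseGeometry:
        return self.geoms[self.ids.index(area_id)]

    def with_properties(self, records: Mapping[str, Mapping[str, Any]]) -> "PolygonLayer":
        """Return a copy whose per-area properties are replaced from ``records``."""
        unknown = set(records) - set(self.ids)
        if unknown:
            raise KeyError(f"unknown area_id(s): {sorted(unknown)}")
        props = [dict(records.get(i, {})) for i in self.ids]
        return PolygonLayer(list(self.ids), list(self.geoms), props)

    def to_geojson(self) -> dict[str, Any]:
        features = []
        for i, g, p in zip(self.ids, self.geoms, self.properties):
            props = {"area_id": i, **p}
            features.append(
                {"type": "Feature", "properties": props, "geometry": geom_mapping(g)}
            )
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_geojson()))

    @classmethod
    def from_geojson(cls, obj: dict[str, Any]) -> "PolygonLayer":
        ids, geoms, props = [], [], []
        for feat in obj["features"]:
            p = dict(feat.get("properties") or {})
            try:
                ids.append(str(p.pop("area_id")))
            except KeyError:
                raise KeyError("every feature needs an 'area_id' property") from None
            geoms.append(geom_shape(feat["geometry"]))
            props.append(p)
        return cls(ids, geoms, props)

    @classmethod
    def read_geojson(cls, path: str | Path) -> "PolygonLayer":
        return cls.from_geojson(json.loads(Path(path).read_text()))
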