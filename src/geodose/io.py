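"""GeoJSON interchange for plumes and population maps.

Plumes are FeatureCollections with one Polygon per contour and a ``level_gy``
property; population maps carry ``id`` and ``population`` properties.  All
coordinates are planar kilometres; a small equirectangular shim converts
lon/lat GeoJSON for users bringing their own ground truth.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .scenario import GroundTruthPlume, Subdivision, SubdivisionMap

__all__ = [
    "plume_to_geojson",
    "plume_from_geojson",
    "map_to_geojson",
    "map_from_geojson",
    "lonlat_to_km",
]

EARTH_RADIUS_KM = 6371.0088


def plume_to_geojson(plume: GroundTruthPlume, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"level_gy": lv},
            "geometry": mapping(ring),
        }
        for lv, ring in plume.contours
    ]
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "epicenter": list(plume.epicenter),
            "bearing_deg": plume.bearing_deg,
            "weather_variant": plume.weather_variant,
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def plume_from_geojson(path: str | Path) -> GroundTruthPlume:
    doc = json.loads(Path(path).read_text())
    props = doc.get("properties", {})
    contours = []
    for f in doc["features"]:
        geom = shape(f["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError("multi-part contours are unsupported; expected Polygon")
        contours.append((float(f["properties"]["level_gy"]), geom))
    contours.sort(key=lambda t: t[0])
    vd = len(contours[0][1].exterior.coords) - 1 if contours else 0
    return GroundTruthPlume(
        epicenter=tuple(props.get("epicenter", (0.0, 0.0))),
        bearing_deg=float(props.get("bearing_deg", 0.0)),
        contours=contours,
        vertex_density=vd,
        weather_variant=props.get("weather_variant", "none"),
    )


def map_to_geojson(smap: SubdivisionMap, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": s.id, "population": s.population},
            "geometry": mapping(s.boundary),
        }
        for s in smap.subdivisions
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def map_from_geojson(path: str | Path) -> SubdivisionMap:
    doc = json.loads(Path(path).read_text())
    subs = []
    for f in doc["features"]:
        geom = shape(f["geometry"])
        subs.append(
            Subdivision(
                id=str(f["properties"]["id"]),
                boundary=geom,
                population=int(f["properties"]["population"]),
            )
        )
    xs = [s.boundary.bounds for s in subs]
    bounds = (
        min(b[0] for b in xs),
        min(b[1] for b in xs),
        max(b[2] for b in xs),
        max(b[3] for b in xs),
    )
    return SubdivisionMap(subdivisions=subs, bounds=bounds)


def lonlat_to_km(lonlat: np.ndarray, origin: tuple[float, float]) -> np.ndarray:
    """Equirectangular projection of lon/lat degrees to planar km."""
    arr = np.asarray(lonlat, dtype=float)
    lon0, lat0 = origin
    x = np.radians(arr[..., 0] - lon0) * EARTH_RADIUS_KM * math.cos(math.radians(lat0))
    y = np.radians(arr[..., 1] - lat0) * EARTH_RADIUS_KM
    return np.stack([x, y], axis=-1)
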