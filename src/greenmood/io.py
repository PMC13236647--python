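"""Flat-file interchange: GeoJSON communities, CSV posts/indicators/tables.

Coordinates are planar meters throughout (no CRS handling); GeoJSON is used
as a geometry container for mapping tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .emotions import GeoPost

__all__ = [
    "write_communities_geojson",
    "read_communities_geojson",
    "write_posts_csv",
    "read_posts_csv",
    "write_indicators_csv",
]


def write_communities_geojson(
    ids: list[str],
    polygons: list[shapely.Geometry],
    properties: dict[str, list] | None = None,
    path: str | Path = "communities.geojson",
) -> None:
    properties = properties or {}
    features = []
    for i, (cid, poly) in enumerate(zip(ids, polygons)):
        props = {"community_id": cid}
        for key, vals in properties.items():
            v = vals[i]
            props[key] = v.item() if hasattr(v, "item") else v
        features.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_communities_geojson(path: str | Path):
    doc = json.loads(Path(path).read_text())
    ids, polys, props = [], [], []
    for feat in doc["features"]:
        ids.append(feat["properties"]["community_id"])
        polys.append(shape(feat["geometry"]))
        props.append(feat["properties"])
    return ids, polys, pd.DataFrame(props).set_index("community_id")


def write_posts_csv(posts: list[GeoPost], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [p.id for p in posts],
            "x": [p.x for p in posts],
            "y": [p.y for p in posts],
            "timestamp": [p.timestamp.isoformat() for p in posts],
            "sentiment": [p.sentiment for p in posts],
        }
    )
    df.to_csv(path, index=False)


def read_posts_csv(path: str | Path) -> list[GeoPost]:
    df = pd.read_csv(path)
    return [
        GeoPost(
            id=str(r.id),
            x=float(r.x),
            y=float(r.y),
            timestamp=pd.to_datetime(r.timestamp).to_pydatetime(),
            sentiment=str(r.sentiment),
        )
        for r in df.itertuples()
    ]


def write_indicators_csv(indicators, path: str | Path) -> None:
    pd.DataFrame(
        {
            "community_id": [e.community_id for e in indicators],
            "season": [e.season for e in indicators],
            "raw_density": [e.raw_density for e in indicators],
            "population": [e.population for e in indicators],
            "index": [e.index for e in indicators],
        }
    ).to_csv(path, index=False)
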