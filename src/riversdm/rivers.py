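"""River networks: order filtering, geodesic length, habitat overlay.

The network is a set of lon/lat polylines, each carrying a Strahler
stream order.  Suitable river length L is obtained by dropping
low-order streams (the study species avoids small rivers), clipping the
remaining lines to the suitable-habitat polygons, and summing
great-circle lengths of the retained pieces.  Segment–polygon
intersections are computed planarly in lon/lat (as in any desktop GIS
overlay); lengths of the clipped pieces are spherical (haversine,
R = 6371.0088 km), so the planar step only decides *where* to cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from shapely.geometry import LineString, MultiLineString, shape, mapping
from shapely.ops import unary_union

from .habitat import HabitatMask

__all__ = [
    "RiverNetwork", "SuitableLength", "EARTH_RADIUS_KM",
    "filter_by_order", "geodesic_length", "clip_to_polygons",
    "suitable_river_length", "read_rivers_geojson", "write_rivers_geojson",
]

#: IUGG mean Earth radius
EARTH_RADIUS_KM = 6371.0088


@dataclass
class RiverNetwork:
    """Polyline features with per-line attributes.

    ``lines`` is a DataFrame with columns id, order (Strahler), name,
    geometry (shapely LineString / MultiLineString in lon/lat).
    """

    lines: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "order", "geometry"}
        missing = required - set(self.lines.columns)
        if missing:
            raise ValueError(f"river table lacks columns: {sorted(missing)}")
        if "name" not in self.lines.columns:
            self.lines = self.lines.assign(name="")
        orders = self.lines["order"]
        if orders.isna().any():
            raise ValueError("missing stream order on some lines")
        if (orders < 1).any():
            raise ValueError("stream order must be ≥ 1")

    def __len__(self) -> int:
        return len(self.lines)

    def total_length_km(self) -> float:
        return float(sum(geodesic_length(g) for g in self.lines["geometry"]))


def filter_by_order(network: RiverNetwork, min_order: int = 6) -> RiverNetwork:
    """Keep only lines whose Strahler order is at least ``min_order``."""
    kept = network.lines[network.lines["order"] >= min_order]
    return RiverNetwork(kept.reset_index(drop=True))


def _haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geodesic_length(line) -> float:
    """Great-circle length of a polyline in km.

    Accepts a LineString, MultiLineString, or an (n, 2) array of
    (lon, lat) vertices; empty geometries have length 0.
    """
    if isinstance(line, MultiLineString):
        return float(sum(geodesic_length(part) for part in line.geoms))
    if isinstance(line, LineString):
        coords = np.asarray(line.coords)
    else:
        coords = np.asarray(line, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("polyline must be (n, 2) lon/lat vertices")
    if len(coords) < 2:
        if len(coords) == 0 and isinstance(line, LineString):
            return 0.0
        raise ValueError("polyline needs at least 2 vertices")
    seg = _haversine_km(coords[:-1, 0], coords[:-1, 1],
                        coords[1:, 0], coords[1:, 1])
    return float(seg.sum())


def clip_to_polygons(network: RiverNetwork, polygons) -> RiverNetwork:
    """Intersect each line with the polygon union; keep inside portions.

    Lines lying exactly on a polygon edge count as inside (shapely
    polygons are closed sets).  Lines with no inside portion are
    dropped; partially-inside lines keep their attributes with the
    clipped geometry.
    """
    if isinstance(polygons, (list, tuple)):
        union = unary_union(polygons) if polygons else None
    else:
        union = polygons
    rows = []
    for _, rec in network.lines.iterrows():
        if union is None or union.is_empty:
            continue
        piece = rec["geometry"].intersection(union)
        if piece.is_empty:
            continue
        # discard stray points from tangential touches
        if piece.geom_type == "GeometryCollection":
            parts = [g for g in piece.geoms
                     if g.geom_type in ("LineString", "MultiLineString")]
            if not parts:
                continue
            piece = unary_union(parts)
        if piece.geom_type not in ("LineString", "MultiLineString"):
            continue
        row = rec.to_dict()
        row["geometry"] = piece
        rows.append(row)
    df = pd.DataFrame(rows, columns=network.lines.columns) if rows else \
        pd.DataFrame(columns=network.lines.columns)
    if len(df) == 0:
        df = df.assign(order=pd.Series(dtype=float))[network.lines.columns]
    return RiverNetwork(df)


@dataclass
class SuitableLength:
    """Total suitable river length L with its per-line breakdown."""

    total_km: float
    per_line: pd.DataFrame          # id, order, name, length_km
    min_order: int
    threshold: float

    def __post_init__(self) -> None:
        assert self.total_km >= 0


def suitable_river_length(network: RiverNetwork, mask: HabitatMask,
                          min_order: int = 6) -> SuitableLength:
    """L = Σ great-circle length of order-filtered lines inside habitat.

    Composition: filter_by_order → clip to the mask's polygons → sum
    geodesic lengths, keeping a per-line breakdown.
    """
    if not mask.polygons and mask.suitable_count:
        raise ValueError("mask has suitable cells but no polygons; "
                         "call polygonize(mask) first")
    filtered = filter_by_order(network, min_order)
    clipped = clip_to_polygons(filtered, mask.polygons)
    if len(clipped):
        per_line = pd.DataFrame({
            "id": clipped.lines["id"],
            "order": clipped.lines["order"],
            "name": clipped.lines["name"],
            "length_km": [geodesic_length(g) for g in clipped.lines["geometry"]],
        })
        total = float(per_line["length_km"].sum())
    else:
        per_line = pd.DataFrame(columns=["id", "order", "name", "length_km"])
        total = 0.0
    return SuitableLength(total, per_line, min_order, mask.threshold)


def read_rivers_geojson(path: str | Path,
                        order_attr: str = "order") -> RiverNetwork:
    """Read a GeoJSON FeatureCollection of line features with an order
    attribute (configurable name, e.g. HydroSHEDS' Strahler field)."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {})
        if order_attr not in props:
            raise ValueError(f"feature {i} lacks order attribute "
                             f"{order_attr!r}")
        rows.append({"id": props.get("id", i),
                     "order": int(props[order_attr]),
                     "name": props.get("name", ""),
                     "geometry": shape(feat["geometry"])})
    return RiverNetwork(pd.DataFrame(rows))


def write_rivers_geojson(network: RiverNetwork, path: str | Path) -> None:
    feats = []
    for _, rec in network.lines.iterrows():
        feats.append({
            "type": "Feature",
            "properties": {"id": rec["id"], "order": int(rec["order"]),
                           "name": rec.get("name", "")},
            "geometry": mapping(rec["geometry"]),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
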