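"""Tract geography: adjacency, buffer filtering, distances, components.

The spatial unit is the census tract. A :class:`TractGraph` bundles the
tract attributes needed downstream (centroid, households, average income,
optional polygon) with an undirected contiguity graph and the hospital
location. Coordinates are (lon, lat) WGS84 degrees throughout; distances
are great-circle kilometres.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
from shapely.geometry import Point, mapping, shape
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class Tract:
    """A census tract with the attributes the catchment analysis uses."""

    tract_id: str
    centroid: tuple[float, float]  # (lon, lat)
    households: int
    avg_income: float
    polygon: object | None = None  # shapely Polygon/MultiPolygon
    county: str | None = None

    def __post_init__(self) -> None:
        if self.households < 0:
            raise ValueError(f"tract {self.tract_id}: households must be >= 0")
        if not -90.0 <= self.centroid[1] <= 90.0:
            raise ValueError(f"tract {self.tract_id}: latitude out of range")


@dataclass
class TractGraph:
    """Tracts plus symmetric, irreflexive contiguity edges and the hospital point.

    ``edges`` stores each unordered pair once as a sorted tuple. Isolated
    tracts (degree 0) are allowed; the intrinsic CAR prior treats them
    separately.
    """

    tracts: dict[str, Tract]
    edges: set[tuple[str, str]] = field(default_factory=set)
    hospital_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on tract {a}")
            if a not in self.tracts or b not in self.tracts:
                raise ValueError(f"edge ({a},{b}) references unknown tract")

    @property
    def tract_ids(self) -> list[str]:
        return sorted(self.tracts)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            return
        self.edges.add((a, b) if a < b else (b, a))

    def degree(self, tract_id: str) -> int:
        return sum(1 for e in self.edges if tract_id in e)

    def degrees(self) -> dict[str, int]:
        m = {t: 0 for t in self.tracts}
        for a, b in self.edges:
            m[a] += 1
            m[b] += 1
        return m

    def neighbors(self, tract_id: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == tract_id:
                out.add(b)
            elif b == tract_id:
                out.add(a)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.tracts)
        g.add_edges_from(self.edges)
        return g

    def hospital_tract(self) -> str | None:
        """Tract containing the hospital point (polygon test, centroid fallback)."""
        if self.hospital_point is None:
            return None
        pt = Point(*self.hospital_point)
        for tid, tr in self.tracts.items():
            if tr.polygon is not None and tr.polygon.covers(pt):
                return tid
        # fall back to the nearest centroid
        return min(
            self.tracts,
            key=lambda t: haversine_km(self.hospital_point, self.tracts[t].centroid),
        )

    def distances_to_hospital(self) -> dict[str, float]:
        if self.hospital_point is None:
            raise ValueError("hospital_point not set")
        return {
            tid: haversine_km(tr.centroid, self.hospital_point)
            for tid, tr in self.tracts.items()
        }


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lon, lat) points (R = 6371.0088 km)."""
    lon1, lat1 = map(math.radians, a)
    lon2, lat2 = map(math.radians, b)
    if not all(map(math.isfinite, (lon1, lat1, lon2, lat2))):
        raise ValueError("coordinates must be finite")
    s = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def build_adjacency(
    tracts: list[Tract],
    rule: str = "queen",
    hospital_point: tuple[float, float] | None = None,
) -> TractGraph:
    """Contiguity graph from tract polygons.

    queen: an edge wherever two polygons share at least one boundary point.
    rook: only where they share a boundary segment of positive length.
    """
    if rule not in ("queen", "rook"):
        raise ValueError(f"unknown contiguity rule {rule!r}")
    seen: set[str] = set()
    for t in tracts:
        if t.tract_id in seen:
            raise ValueError(f"duplicate tract_id {t.tract_id}")
        seen.add(t.tract_id)
        if t.polygon is None:
            raise ValueError(f"tract {t.tract_id}: polygon required for adjacency")
        if not t.polygon.is_valid:
            raise ValueError(f"tract {t.tract_id}: invalid polygon")

    graph = TractGraph({t.tract_id: t for t in tracts}, hospital_point=hospital_point)
    geoms = [t.polygon for t in tracts]
    tree = STRtree(geoms)
    for i, gi in enumerate(geoms):
        for j in tree.query(gi):
            j = int(j)
            if j <= i:
                continue
            inter = gi.intersection(geoms[j])
            if inter.is_empty:
                continue
            if rule == "queen" or inter.length > 0.0:
                graph.add_edge(tracts[i].tract_id, tracts[j].tract_id)
    return graph


def _polygon_min_distance_km(
    polygon, point: tuple[float, float], samples_per_edge: int = 64
) -> float:
    """Min great-circle distance from a point to sampled polygon boundary points.

    The buffer circle is defined in great-circle distance, so plane geometry
    is avoided: vertices plus evenly spaced points along every edge are tested.
    """
    boundaries = (
        [polygon.exterior] + list(polygon.interiors)
        if polygon.geom_type == "Polygon"
        else [ring for part in polygon.geoms for ring in ([part.exterior] + list(part.interiors))]
    )
    best = math.inf
    for ring in boundaries:
        coords = list(ring.coords)
        for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
            for k in range(samples_per_edge):
                f = k / samples_per_edge
                p = (x0 + f * (x1 - x0), y0 + f * (y1 - y0))
                d = haversine_km(p, point)
                if d < best:
                    best = d
    return best


def filter_buffer(graph: TractGraph, radius_km: float) -> TractGraph:
    """Restrict to tracts within a circular buffer around the hospital.

    With polygons, a tract is kept when its polygon intersects the circle
    (boundary sampled in great-circle distance, or the hospital lies inside);
    without polygons, when the centroid is within ``radius_km``.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    if graph.hospital_point is None:
        raise ValueError("hospital_point not set")
    hp = graph.hospital_point
    hp_geom = Point(*hp)

    kept: dict[str, Tract] = {}
    for tid, tr in graph.tracts.items():
        if tr.polygon is not None:
            inside = tr.polygon.covers(hp_geom) or (
                _polygon_min_distance_km(tr.polygon, hp) <= radius_km
            )
        else:
            inside = haversine_km(tr.centroid, hp) <= radius_km
        if inside:
            kept[tid] = tr
    if not kept:
        raise ValueError("no tracts within buffer")
    edges = {(a, b) for a, b in graph.edges if a in kept and b in kept}
    log.info(
        "buffer %.1f km: kept %d of %d tracts", radius_km, len(kept), len(graph.tracts)
    )
    return TractGraph(kept, edges, hospital_point=hp)


def connected_components(graph: TractGraph, subset: set[str]) -> list[set[str]]:
    """Partition ``subset`` into maximal connected sets under edges restricted to it."""
    unknown = subset - set(graph.tracts)
    if unknown:
        raise ValueError(f"unknown tract ids: {sorted(unknown)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(subset)
    g.add_edges_from((a, b) for a, b in graph.edges if a in subset and b in subset)
    return [set(c) for c in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# I/O


def read_geojson(path, hospital_point=None) -> TractGraph:
    """Load tracts from a GeoJSON FeatureCollection and build queen adjacency.

    Feature properties must include tract_id, households, avg_income.
    """
    with open(path) as fh:
        fc = json.load(fh)
    tracts = []
    for feat in fc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        c = geom.centroid
        tracts.append(
            Tract(
                tract_id=str(props["tract_id"]),
                centroid=(c.x, c.y),
                households=int(props["households"]),
                avg_income=float(props["avg_income"]),
                polygon=geom,
                county=props.get("county"),
            )
        )
    hp = hospital_point or tuple(fc.get("hospital_point", ())) or None
    return build_adjacency(tracts, rule="queen", hospital_point=hp)


def write_geojson(graph: TractGraph, path, extra_properties=None) -> None:
    """Write tracts (with polygons where present) as a GeoJSON FeatureCollection."""
    extra_properties = extra_properties or {}
    feats = []
    for tid, tr in sorted(graph.tracts.items()):
        geom = (
            mapping(tr.polygon)
            if tr.polygon is not None
            else {"type": "Point", "coordinates": list(tr.centroid)}
        )
        props = {
            "tract_id": tid,
            "households": tr.households,
            "avg_income": tr.avg_income,
        }
        props.update(extra_properties.get(tid, {}))
        feats.append({"type": "Feature", "properties": props, "geometry": geom})
    fc = {"type": "FeatureCollection", "features": feats}
    if graph.hospital_point is not None:
        fc["hospital_point"] = list(graph.hospital_point)
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_edge_list(path) -> set[tuple[str, str]]:
    """Adjacency from a CSV edge list with header ``tract_a,tract_b``."""
    edges = set()
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            a, b = row["tract_a"], row["tract_b"]
            if a != b:
                edges.add((a, b) if a < b else (b, a))
    return edges


def write_summary_csv(graph: TractGraph, path, radius_km: float | None = None) -> None:
    """Per-tract CSV: tract_id, degree, distance_km, in_buffer."""
    degs = graph.degrees()
    dists = graph.distances_to_hospital()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tract_id", "degree", "distance_km", "in_buffer"])
        for tid in graph.tract_ids:
            in_buf = "" if radius_km is None else int(dists[tid] <= radius_km)
            w.writerow([tid, degs[tid], f"{dists[tid]:.3f}", in_buf])


def subgraph(graph: TractGraph, keep: set[str]) -> TractGraph:
    """Induced subgraph on ``keep`` (hospital point preserved)."""
    unknown = keep - set(graph.tracts)
    if unknown:
        raise ValueError(f"unknown tract ids: {sorted(unknown)[:5]}")
    return TractGraph(
        {t: replace(graph.tracts[t]) for t in keep},
        {(a, b) for a, b in graph.edges if a in keep and b in keep},
        hospital_point=graph.hospital_point,
    )
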