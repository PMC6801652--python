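"""Access metrics: network distance, travel time, facility density.

The coder's output includes simple accessibility measures from a point of
interest (a home, a school) to the surrounding facilities: road-network
distance in kilometres, walking and cycling time in minutes, and counts
of facilities within a radius.  Without a road network the network
distance is approximated by the great-circle distance times a detour
factor, the standard street-grid correction.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geo_grid import GeoPoint, haversine_km

WALK_KMH = 5.0
CYCLE_KMH = 15.0
DETOUR_FACTOR = 1.3
SNAP_TOLERANCE_M = 200.0


@dataclass
class RoadNetwork:
    """Undirected road graph with projected node coordinates (metres)."""

    graph: nx.Graph
    _tree: cKDTree = field(init=False, repr=False)
    _node_ids: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if data.get("length_m", 0) <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive length")
        self._node_ids = list(self.graph.nodes)
        coords = np.array([self.graph.nodes[n]["xy"] for n in self._node_ids], dtype=float)
        self._tree = cKDTree(coords)

    @classmethod
    def from_edges(
        cls,
        nodes: dict,
        edges: Iterable[tuple],
    ) -> "RoadNetwork":
        """Build from ``{node_id: (x, y)}`` and ``(u, v, length_m)`` triples."""
        g = nx.Graph()
        for nid, xy in nodes.items():
            g.add_node(nid, xy=(float(xy[0]), float(xy[1])))
        for u, v, length in edges:
            if u not in g or v not in g:
                raise ValueError(f"edge ({u}, {v}) references an unknown node")
            g.add_edge(u, v, length_m=float(length))
        return cls(graph=g)

    @classmethod
    def from_csv(cls, node_path: str, edge_path: str) -> "RoadNetwork":
        """Load ``id,x,y`` node CSV and ``u,v,length_m`` edge CSV."""
        nodes: dict[str, tuple[float, float]] = {}
        with open(node_path, newline="") as fh:
            for row in csv.DictReader(fh):
                nodes[row["id"]] = (float(row["x"]), float(row["y"]))
        edges = []
        with open(edge_path, newline="") as fh:
            for row in csv.DictReader(fh):
                edges.append((row["u"], row["v"], float(row["length_m"])))
        return cls.from_edges(nodes, edges)

    @classmethod
    def from_geojson(cls, path: str) -> "RoadNetwork":
        """Build from LineString features with projected coordinates.

        Consecutive vertices become edges; segment lengths are computed
        from the coordinates.
        """
        with open(path) as fh:
            data = json.load(fh)
        nodes: dict[tuple, tuple[float, float]] = {}
        edges = []
        for feat in data.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "LineString":
                continue
            coords = geom["coordinates"]
            for a, b in zip(coords, coords[1:]):
                ka, kb = tuple(a), tuple(b)
                nodes[ka] = (a[0], a[1])
                nodes[kb] = (b[0], b[1])
                length = math.dist(a[:2], b[:2])
                if length > 0:
                    edges.append((ka, kb, length))
        return cls.from_edges(nodes, edges)

    def snap(self, xy: Sequence[float], tolerance_m: float = SNAP_TOLERANCE_M):
        """Nearest node within tolerance; returns (node_id, offset_m)."""
        dist, idx = self._tree.query([float(xy[0]), float(xy[1])])
        if dist > tolerance_m:
            raise ValueError(
                f"point {tuple(xy)} is {dist:.0f} m from the nearest road node "
                f"(tolerance {tolerance_m:.0f} m)"
            )
        return self._node_ids[int(idx)], float(dist)


def route_distance_km(
    net: Optional[RoadNetwork],
    a,
    b,
    detour_factor: float = DETOUR_FACTOR,
    snap_tolerance_m: float = SNAP_TOLERANCE_M,
) -> float:
    """Travel distance between two points, in kilometres.

    With a network: shortest-path length between the snapped nodes plus
    both snap offsets (points given as projected ``(x, y)``).  Without:
    great-circle distance times the detour factor (points given as
    :class:`GeoPoint`).
    """
    if net is None:
        return haversine_km(a, b) * detour_factor
    na, off_a = net.snap(a, snap_tolerance_m)
    nb, off_b = net.snap(b, snap_tolerance_m)
    path_m = nx.shortest_path_length(net.graph, na, nb, weight="length_m")
    return (path_m + off_a + off_b) / 1000.0


def travel_minutes(dist_km: float, mode: str, speeds_kmh: Optional[dict] = None) -> float:
    """Travel time in minutes for ``mode`` in {"walk", "cycle"}."""
    if dist_km < 0:
        raise ValueError("distance must be non-negative")
    speeds = {"walk": WALK_KMH, "cycle": CYCLE_KMH}
    if speeds_kmh:
        speeds.update(speeds_kmh)
    if mode not in speeds:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(speeds)}")
    return dist_km / speeds[mode] * 60.0


@dataclass
class DensityResult:
    count: int
    nearest: Optional[object]
    nearest_km: Optional[float]
    radius_m: float


def facility_density(
    centre: GeoPoint,
    radius_m: float,
    facilities: Sequence,
    category=None,
) -> DensityResult:
    """Count facilities within a great-circle radius of a centre point.

    A facility exactly at the radius counts as inside.  The nearest
    facility overall (category-filtered) is reported even when it lies
    beyond the radius.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    pool = [f for f in facilities if category is None or f.category == category]
    count = 0
    nearest = None
    nearest_km = None
    for f in pool:
        d = haversine_km(centre, f.location)
        if d * 1000.0 <= radius_m:
            count += 1
        if nearest_km is None or d < nearest_km:
            nearest, nearest_km = f, d
    return DensityResult(count=count, nearest=nearest, nearest_km=nearest_km, radius_m=radius_m)
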