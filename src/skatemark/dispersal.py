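"""Dispersal distances between successive captures of an individual.

A recaptured skate's displacement is the great-circle distance between the
two capture positions when the straight track stays in water.  When the
track would cross land, the distance is instead the shortest path through a
water-only network: a regular triangular lattice (default triangle area
0.3 km^2) whose edges crossing land have been erased, so paths are forced
around headlands and islands.

The network lives in the shared equal-area planar frame (km).  Shortest
paths use uniform-cost search with lexicographic node-id tie-breaking, so
both distances and node paths are reproducible.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point
from shapely.prepared import prep

from .projection import EARTH_RADIUS_KM, LambertEqualArea

if TYPE_CHECKING:
    from .histories import CaptureHistory

logger = logging.getLogger(__name__)


def geodesic_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lon, lat) points.

    Haversine on a sphere of radius 6371.0088 km; symmetric, zero iff the
    points coincide.
    """
    lon1, lat1 = map(math.radians, p1)
    lon2, lat2 = map(math.radians, p2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def segment_crosses_land(
    p1: tuple[float, float],
    p2: tuple[float, float],
    land,
    projection: LambertEqualArea,
) -> bool:
    """True iff the straight projected track between two points enters land.

    Endpoints or tangential grazes touching the coastline boundary do not
    count; only interior-interior intersection does.
    """
    seg = LineString([projection.forward(*p1), projection.forward(*p2)])
    if seg.length == 0.0:
        return False
    land_p = projection.project_geometry(land)
    return seg.relate_pattern(land_p, "T********")


def triangle_edge_length_km(triangle_area_km2: float) -> float:
    """Side length of an equilateral triangle of the given area."""
    return math.sqrt(4.0 * triangle_area_km2 / math.sqrt(3.0))


@dataclass
class WaterNetwork:
    """Water-only graph over a triangular lattice in the projected km frame.

    Nodes are integer ids with ``pos`` (x, y) attributes; undirected edges
    carry their Euclidean ``length`` in km.
    """

    graph: nx.Graph
    triangle_area_km2: float
    edge_length_km: float
    projection: LambertEqualArea
    _tree_cache: Optional[tuple[cKDTree, list[int]]] = None

    def node_positions(self) -> tuple[np.ndarray, list[int]]:
        nodes = sorted(self.graph.nodes)
        pos = np.array([self.graph.nodes[n]["pos"] for n in nodes])
        return pos, nodes

    def node_tree(self) -> tuple[cKDTree, list[int]]:
        if self._tree_cache is None:
            pos, nodes = self.node_positions()
            self._tree_cache = (cKDTree(pos), nodes)
        return self._tree_cache


def build_water_network(
    extent_lonlat,
    land_lonlat,
    triangle_area_km2: float,
    projection: Optional[LambertEqualArea] = None,
) -> WaterNetwork:
    """Triangular water lattice over the extent with land edges erased.

    Lattice rows run parallel to the projected x-axis, anchored at the
    extent's lower-left corner; interior nodes have degree 6.  Any edge whose
    segment intersects the land interior (positive overlap length, or lying
    inside land) is removed; isolated nodes are dropped.
    """
    from .projection import projection_for

    proj = projection or projection_for(extent_lonlat)
    extent = proj.project_geometry(extent_lonlat)
    land = proj.project_geometry(land_lonlat) if land_lonlat is not None else None
    s = triangle_edge_length_km(triangle_area_km2)
    dy = s * math.sqrt(3.0) / 2.0
    minx, miny, maxx, maxy = extent.bounds
    n_rows = int(math.ceil((maxy - miny) / dy)) + 1
    n_cols = int(math.ceil((maxx - minx) / s)) + 2

    g = nx.Graph()
    coords: dict[int, tuple[float, float]] = {}

    def node_id(i: int, j: int) -> int:
        return j * n_cols + i

    extent_prep = prep(extent)
    for j in range(n_rows):
        y = miny + j * dy
        offset = (s / 2.0) if (j % 2) else 0.0
        for i in range(n_cols):
            x = minx + i * s - offset
            coords[node_id(i, j)] = (x, y)

    land_prep = prep(land) if land is not None and not land.is_empty else None

    def edge_ok(a: int, b: int) -> bool:
        pa, pb = coords[a], coords[b]
        mid = Point((pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0)
        if not extent_prep.intersects(mid):
            return False
        if land_prep is None:
            return True
        seg = LineString([pa, pb])
        if not land_prep.intersects(seg):
            return True
        inter = seg.intersection(land)
        return inter.length <= 1e-9 and not seg.within(land)

    for j in range(n_rows):
        odd = j % 2
        for i in range(n_cols):
            a = node_id(i, j)
            if i + 1 < n_cols:
                _maybe_add(g, coords, a, node_id(i + 1, j), edge_ok)
            if j + 1 < n_rows:
                _maybe_add(g, coords, a, node_id(i, j + 1), edge_ok)
                # the second up-neighbour alternates with row parity
                i2 = i - 1 if odd else i + 1
                if 0 <= i2 < n_cols:
                    _maybe_add(g, coords, a, node_id(i2, j + 1), edge_ok)

    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    if g.number_of_edges() == 0:
        raise ValueError("water region is empty: no lattice edge survives land erasure")
    return WaterNetwork(g, triangle_area_km2, s, proj)


def _maybe_add(g, coords, a, b, edge_ok):
    if edge_ok(a, b):
        pa, pb = coords[a], coords[b]
        for n, p in ((a, pa), (b, pb)):
            if n not in g:
                g.add_node(n, pos=p)
        g.add_edge(a, b, length=math.hypot(pb[0] - pa[0], pb[1] - pa[1]))


def uniform_cost_search(
    graph: nx.Graph, source: int, target: int
) -> tuple[float, list[int]]:
    """Dijkstra with (cost, node-id) heap ordering: lexicographic tie-break.

    Returns (distance, node path); raises ``nx.NetworkXNoPath`` when the
    target is unreachable.
    """
    dist = {source: 0.0}
    prev: dict[int, int] = {}
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        if u == target:
            path = [u]
            while path[-1] != source:
                path.append(prev[path[-1]])
            return d, path[::-1]
        done.add(u)
        for v, attrs in graph[u].items():
            nd = d + attrs["length"]
            if v not in dist or nd < dist[v] - 1e-15 or (
                abs(nd - dist[v]) <= 1e-15 and prev.get(v, v) > u
            ):
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    raise nx.NetworkXNoPath(f"no path {source} -> {target}")


def shortest_water_path(
    net: WaterNetwork,
    p1: tuple[float, float],
    p2: tuple[float, float],
) -> tuple[float, list[int]]:
    """Marine distance between two lon/lat points through the water network.

    Both endpoints are snapped to their nearest network node; the two snap
    offsets are added to the path length.  An endpoint farther than two edge
    lengths from any node is rejected (it is probably on land or outside the
    modelled extent); endpoints in different components raise with both
    component sizes named.
    """
    tree, nodes = net.node_tree()
    q1 = np.array(net.projection.forward(*p1))
    q2 = np.array(net.projection.forward(*p2))
    (d1, i1), (d2, i2) = tree.query(q1), tree.query(q2)
    for off, pt in ((d1, p1), (d2, p2)):
        if off > 2.0 * net.edge_length_km:
            raise ValueError(
                f"point {pt} is {off:.2f} km from the nearest water node "
                f"(> 2 edge lengths); on land or outside the extent?"
            )
    a, b = nodes[int(i1)], nodes[int(i2)]
    if a == b:
        return float(d1 + d2) if not np.allclose(q1, q2) else 0.0, [a]
    try:
        path_km, path = uniform_cost_search(net.graph, a, b)
    except nx.NetworkXNoPath:
        comp_a = len(nx.node_connected_component(net.graph, a))
        comp_b = len(nx.node_connected_component(net.graph, b))
        raise ValueError(
            f"no water path: endpoints lie in different components "
            f"(sizes {comp_a} and {comp_b})"
        )
    return float(path_km + d1 + d2), path


@dataclass
class DispersalResult:
    individual_id: str
    interval_index: int
    method: str  # "straight" | "marine"
    distance_km: float
    days: int


def dispersal_distances(
    history: "CaptureHistory",
    land_lonlat,
    net: Optional[WaterNetwork],
    projection: Optional[LambertEqualArea] = None,
) -> list[DispersalResult]:
    """One distance per successive pair of dated, located events.

    Straight-line (great-circle) when the track stays in water; shortest
    water-network path when it crosses land.  Intervals with a missing
    coordinate are skipped with a logged reason.
    """
    proj = projection or (net.projection if net is not None else None)
    results: list[DispersalResult] = []
    dated = [e for e in history.events if e.date is not None]
    for k in range(len(dated) - 1):
        e0, e1 = dated[k], dated[k + 1]
        if not (e0.has_coordinates and e1.has_coordinates):
            logger.info(
                "%s interval %d skipped: missing coordinates", history.individual_id, k
            )
            continue
        p0, p1 = (e0.lon, e0.lat), (e1.lon, e1.lat)
        days = (e1.date - e0.date).days
        if land_lonlat is not None and proj is not None and segment_crosses_land(
            p0, p1, land_lonlat, proj
        ):
            if net is None:
                logger.warning(
                    "%s interval %d crosses land but no water network supplied",
                    history.individual_id, k,
                )
                continue
            dist, _ = shortest_water_path(net, p0, p1)
            method = "marine"
        else:
            dist = geodesic_km(p0, p1)
            method = "straight"
        results.append(DispersalResult(history.individual_id, k, method, dist, days))
    return results
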