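"""Hybrid road/rail transportation network with travel-time shortest paths.

Raw transportation data arrive as bare polyline segments in five categories
(secondary way, primary way, highway, railway, high-speed railway) that are
not topologically related, and the railway subnetwork is physically separate
from the road subnetwork. Topology building proceeds in two steps:

1. every railway station is connected by two *link edges* — one to the
   nearest road segment and one to the nearest railway segment, each split
   at the projection point — so the two subnetworks become navigable as one;
2. segment endpoints within a snap tolerance are merged into shared nodes
   and the nodes are numbered consecutively from 1.

Per-edge travel time is the segment length divided by the category speed
limit, so shortest paths minimize travel time, not distance. Road endpoints
are never merged with rail endpoints: rail is reachable only through
stations, mirroring how passengers actually enter the railway network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import CATEGORIES, DEFAULT_SPEED_TABLE, RAIL_CATEGORIES
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "TransportSegment",
    "Station",
    "TransportGraph",
    "TravelTimeMatrix",
    "segment_travel_time",
    "great_circle_km",
    "polyline_length_km",
    "build_graph",
    "snap_to_network",
    "shortest_time_matrix",
]


def great_circle_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Haversine great-circle distance in kilometers."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def polyline_length_km(polyline) -> float:
    """Great-circle length of a lon/lat polyline, km."""
    pts = list(polyline)
    return sum(
        great_circle_km(*pts[i], *pts[i + 1]) for i in range(len(pts) - 1)
    )


def segment_travel_time(
    length_km: float, category: str, speed_table: dict[str, float] | None = None
) -> float:
    """Travel time in hours: segment length divided by the category speed limit."""
    speed_table = DEFAULT_SPEED_TABLE if speed_table is None else speed_table
    if category not in speed_table:
        raise ConfigurationError(f"unknown transportation category {category!r}")
    speed = speed_table[category]
    if speed <= 0:
        raise ConfigurationError(f"non-positive speed for category {category!r}")
    if length_km < 0:
        raise InputError("segment length must be non-negative")
    return length_km / speed


@dataclass
class TransportSegment:
    """A polyline segment of one transportation category.

    ``length_km`` is taken from the data when provided (surveyed lengths),
    otherwise computed as the great-circle polyline length.
    """

    id: str
    polyline: tuple[tuple[float, float], ...]
    category: str
    length_km: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InputError(
                f"segment {self.id!r}: category {self.category!r} not in {CATEGORIES}"
            )
        self.polyline = tuple((float(x), float(y)) for x, y in self.polyline)
        if len(self.polyline) < 2:
            raise InputError(f"segment {self.id!r}: polyline needs >= 2 points")
        if self.length_km is None:
            self.length_km = polyline_length_km(self.polyline)
        if self.length_km <= 0:
            raise InputError(f"segment {self.id!r}: length must be positive")

    @property
    def is_rail(self) -> bool:
        return self.category in RAIL_CATEGORIES

    def travel_time(self, speed_table: dict[str, float] | None = None) -> float:
        return segment_travel_time(self.length_km, self.category, speed_table)


@dataclass
class Station:
    """A railway station point joining the road and rail subnetworks."""

    id: str
    lon: float
    lat: float


@dataclass
class TravelTimeMatrix:
    """Origin x destination shortest travel times, hours."""

    origins: list
    destinations: list
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (len(self.origins), len(self.destinations)):
            raise InputError("travel time matrix shape mismatch")

    def time(self, origin, destination) -> float:
        return float(
            self.times[self.origins.index(origin), self.destinations.index(destination)]
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.times, index=self.origins, columns=self.destinations)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="origin")

    @classmethod
    def from_csv(cls, path) -> "TravelTimeMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class TransportGraph:
    """Undirected travel-time graph with 1-based consecutive node ids."""

    graph: nx.MultiGraph
    coords: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_array(self) -> tuple[np.ndarray, np.ndarray]:
        """(ids, coords) arrays sorted by node id."""
        ids = np.array(sorted(self.coords), dtype=int)
        xy = np.array([self.coords[i] for i in ids], dtype=float)
        return ids, xy


# ---------------------------------------------------------------------------
# topology building


def _project_to_polyline(point, polyline):
    """Nearest point on a polyline (planar lon/lat) -> (dist, arc_s, (x, y)).

    ``arc_s`` is the arc-length position of the projection in the polyline's
    own planar parameterization, used only for ordering splits.
    """
    px, py = point
    best = (math.inf, 0.0, polyline[0])
    s0 = 0.0
    for (x1, y1), (x2, y2) in zip(polyline[:-1], polyline[1:]):
        dx, dy = x2 - x1, y2 - y1
        seg_len = math.hypot(dx, dy)
        if seg_len == 0:
            t = 0.0
        else:
            t = ((px - x1) * dx + (py - y1) * dy) / (seg_len * seg_len)
            t = min(1.0, max(0.0, t))
        qx, qy = x1 + t * dx, y1 + t * dy
        d = math.hypot(px - qx, py - qy)
        if d < best[0]:
            best = (d, s0 + t * seg_len, (qx, qy))
        s0 += seg_len
    return best


def _split_polyline(polyline, arc_positions):
    """Split a polyline at planar arc-length positions -> list of pieces.

    Each piece is (sub_polyline, planar_fraction) where the fractions sum
    to 1; real lengths are apportioned by these fractions.
    """
    pts = list(polyline)
    total = sum(
        math.hypot(x2 - x1, y2 - y1) for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:])
    )
    cuts = sorted(set(arc_positions))
    pieces = []
    cur_piece = [pts[0]]
    s0 = 0.0
    ci = 0
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        seg_len = math.hypot(x2 - x1, y2 - y1)
        while ci < len(cuts) and s0 < cuts[ci] <= s0 + seg_len + 1e-15:
            t = (cuts[ci] - s0) / seg_len if seg_len > 0 else 0.0
            qx, qy = x1 + t * (x2 - x1), y1 + t * (y2 - y1)
            cur_piece.append((qx, qy))
            pieces.append(cur_piece)
            cur_piece = [(qx, qy)]
            ci += 1
        cur_piece.append((x2, y2))
        s0 += seg_len
    while ci < len(cuts):  # float drift pushed a cut past the end: cut there
        pieces.append(cur_piece)
        cur_piece = [cur_piece[-1], cur_piece[-1]]
        ci += 1
    pieces.append(cur_piece)
    # drop duplicate interior points; keep piece count aligned with cuts
    cleaned = []
    for piece in pieces:
        out = [piece[0]]
        for p in piece[1:]:
            if p != out[-1]:
                out.append(p)
        if len(out) < 2:
            out = [piece[0], piece[0]]
        cleaned.append(out)
    lengths = [
        sum(math.hypot(x2 - x1, y2 - y1) for (x1, y1), (x2, y2) in zip(p[:-1], p[1:]))
        for p in cleaned
    ]
    tot = sum(lengths)
    fracs = [l / tot if tot > 0 else 1.0 / len(cleaned) for l in lengths]
    return list(zip(cleaned, fracs))


class _NodeRegistry:
    """Merges coordinates within a snap tolerance, per subnetwork mode."""

    def __init__(self, tolerance: float):
        self.tolerance = tolerance
        self.points: list[tuple[str, float, float]] = []  # (mode, x, y)

    def add(self, mode: str, x: float, y: float) -> int:
        self.points.append((mode, float(x), float(y)))
        return len(self.points) - 1

    def resolve(self) -> tuple[dict[int, int], dict[int, tuple[float, float]]]:
        """Union points within tolerance (same mode); return raw->node-id map.

        Node ids are consecutive from 1, assigned by sorting cluster
        representative coordinates (a canonical traversal) so that the same
        input always yields the same numbering.
        """
        n = len(self.points)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

        by_mode: dict[str, list[int]] = {}
        for idx, (mode, _, _) in enumerate(self.points):
            by_mode.setdefault(mode, []).append(idx)
        for mode, idxs in by_mode.items():
            if mode == "station" or len(idxs) < 2:
                continue  # station nodes are identity nodes, never merged
            xy = np.array([(self.points[i][1], self.points[i][2]) for i in idxs])
            tree = cKDTree(xy)
            for a, b in tree.query_pairs(r=self.tolerance):
                union(idxs[a], idxs[b])

        clusters: dict[int, list[int]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        reps = []
        for root, members in clusters.items():
            xs = [self.points[i][1] for i in members]
            ys = [self.points[i][2] for i in members]
            mode = self.points[root][0]
            reps.append((min(xs), min(ys), mode, root, (float(np.mean(xs)), float(np.mean(ys)))))
        reps.sort(key=lambda r: (r[0], r[1], r[2]))
        raw_to_node: dict[int, int] = {}
        coords: dict[int, tuple[float, float]] = {}
        for node_id, (_, _, _, root, centroid) in enumerate(reps, start=1):
            coords[node_id] = centroid
            for m in clusters[root]:
                raw_to_node[m] = node_id
        return raw_to_node, coords


def build_graph(
    segments: list[TransportSegment],
    stations: list[Station] = (),
    *,
    speed_table: dict[str, float] | None = None,
    snap_tolerance: float = 1e-6,
    transfer_penalty_hours: float = 0.0,
) -> TransportGraph:
    """Build the topologically connected hybrid network.

    Stations split their nearest road and railway segments at the projection
    points and are joined to both by link edges of ``transfer_penalty_hours``
    travel time (0 by default). Segment endpoints within ``snap_tolerance``
    degrees merge into one node, separately for the road and rail subnetworks.
    Node ids are consecutive integers from 1, deterministic for fixed input.
    """
    if not segments:
        raise InputError("build_graph requires at least one segment")
    if snap_tolerance <= 0:
        raise InputError("snap_tolerance must be positive")
    speed_table = DEFAULT_SPEED_TABLE if speed_table is None else speed_table

    rail_segments = [s for s in segments if s.is_rail]
    road_segments = [s for s in segments if not s.is_rail]

    # station -> (segment, arc position) for its nearest road and rail segment
    splits: dict[str, list[tuple[float, str]]] = {}
    station_targets: dict[str, list[tuple[str, float]]] = {}
    for st in stations:
        if not rail_segments:
            raise InputError(
                f"station {st.id!r}: no railway segment present to link to"
            )
        if not road_segments:
            raise InputError(
                f"station {st.id!r}: no road segment present to link to"
            )
        targets = []
        for pool in (road_segments, rail_segments):
            best = min(
                (
                    (*_project_to_polyline((st.lon, st.lat), seg.polyline)[:2], seg.id)
                    for seg in pool
                ),
                key=lambda t: (t[0], t[2]),
            )
            _, arc_s, seg_id = best
            splits.setdefault(seg_id, []).append((arc_s, st.id))
            targets.append((seg_id, arc_s))
        station_targets[st.id] = targets

    registry = _NodeRegistry(snap_tolerance)
    edges = []  # (raw_u, raw_v, time, length_frac_km, segment id, category)
    # raw node index of the split point (segment id, arc_s) for link edges
    split_nodes: dict[tuple[str, float], int] = {}

    for seg in segments:
        mode = "rail" if seg.is_rail else "road"
        t_total = seg.travel_time(speed_table)
        pts = list(seg.polyline)
        planar_total = sum(
            math.hypot(x2 - x1, y2 - y1)
            for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:])
        )
        eps = 1e-9 * max(planar_total, 1.0)
        cut_list = sorted({s for s, _ in splits.get(seg.id, [])})
        interior = [s for s in cut_list if eps < s < planar_total - eps]
        if interior:
            pieces = _split_polyline(seg.polyline, interior)
        else:
            pieces = [(pts, 1.0)]
        piece_nodes = []
        for piece, _ in pieces:
            u = registry.add(mode, *piece[0])
            v = registry.add(mode, *piece[-1])
            piece_nodes.append((u, v))
        for s_pos in cut_list:
            if s_pos <= eps:  # projection at segment start: no split needed
                split_nodes[(seg.id, s_pos)] = piece_nodes[0][0]
            elif s_pos >= planar_total - eps:
                split_nodes[(seg.id, s_pos)] = piece_nodes[-1][1]
            else:
                split_nodes[(seg.id, s_pos)] = piece_nodes[interior.index(s_pos)][1]
        for (piece, frac), (u, v) in zip(pieces, piece_nodes):
            edges.append(
                (u, v, t_total * frac, seg.length_km * frac, seg.id, seg.category)
            )

    for st in stations:
        raw_st = registry.add("station", st.lon, st.lat)
        for seg_id, arc_s in station_targets[st.id]:
            raw_target = split_nodes[(seg_id, arc_s)]
            edges.append(
                (raw_st, raw_target, transfer_penalty_hours, 0.0, f"link:{st.id}:{seg_id}", "link")
            )

    raw_to_node, coords = registry.resolve()
    g = nx.MultiGraph()
    for node_id, xy in coords.items():
        g.add_node(node_id, x=xy[0], y=xy[1])
    for u, v, t, length, seg_id, category in edges:
        g.add_edge(
            raw_to_node[u],
            raw_to_node[v],
            time=float(t),
            length_km=float(length),
            segment=seg_id,
            category=category,
        )
    return TransportGraph(graph=g, coords=coords)


def snap_to_network(
    graph: TransportGraph,
    point: tuple[float, float],
    warn_distance: float | None = None,
) -> int:
    """Nearest graph node to ``point`` by Euclidean distance in degrees.

    Ties are broken by the smallest node id. A warning is logged when the
    snap distance exceeds ``warn_distance`` (same units as the coordinates).
    """
    if graph.n_nodes == 0:
        raise InputError("cannot snap to an empty graph")
    ids, xy = graph.node_array()
    d2 = np.sum((xy - np.asarray(point, dtype=float)) ** 2, axis=1)
    best = d2.min()
    # ids are sorted ascending, so the first minimum is the smallest id
    node = int(ids[int(np.argmax(d2 == best))])
    if warn_distance is not None and math.sqrt(best) > warn_distance:
        logger.warning(
            "point %s snapped to node %d at distance %.6f (> %.6f)",
            point, node, math.sqrt(best), warn_distance,
        )
    return node


def shortest_time_matrix(
    graph: TransportGraph, origin_nodes: list[int], dest_nodes: list[int]
) -> TravelTimeMatrix:
    """All shortest travel times (Dijkstra) between origin and dest nodes, hours."""
    g = graph.graph
    for n in list(origin_nodes) + list(dest_nodes):
        if n not in g:
            raise InputError(f"node {n} not in graph")
    times = np.empty((len(origin_nodes), len(dest_nodes)))
    dest_list = list(dest_nodes)
    for i, o in enumerate(origin_nodes):
        dist = nx.single_source_dijkstra_path_length(g, o, weight="time")
        for j, d in enumerate(dest_list):
            if d not in dist:
                comps = [sorted(c) for c in nx.connected_components(g)]
                raise InputError(
                    f"no path from node {o} to node {d}; "
                    f"graph has {len(comps)} connected components: "
                    + "; ".join(str(c[:8]) for c in comps)
                )
            times[i, j] = dist[d]
    return TravelTimeMatrix(list(origin_nodes), dest_list, times)
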