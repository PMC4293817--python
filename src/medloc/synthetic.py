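"""Seeded synthetic instances: cities, hospitals and hybrid networks.

The reference study area (a Chinese province with 17 prefecture cities, 38
tertiary hospitals and a mixed road/rail network whose length shares are
roughly 42/13/31/10.5/2.3 percent across secondary way, primary way,
highway, railway and high-speed railway) is not publicly available, so this
module generates structurally comparable instances:

* cities placed by blue-noise (minimum-separation) sampling in a bounding
  box, with skewed populations;
* a planar road network — a Gabriel graph over cities plus waypoints —
  whose edges are labeled with road categories so realized length shares
  approximate the configured mix;
* one railway and one high-speed-railway corridor threaded through the
  most populous cities, joined to the roads only via stations (high-speed
  rail aggregates demand along the corridor, which the generator must be
  able to reproduce);
* hospitals allocated to cities with a population-skewed distribution and
  aggregated into one candidate facility per city.

Everything is reproducible from the seed. Two fixed, hand-written instances
are also provided: an 8-city/2-facility micro instance small enough for
exhaustive enumeration, and a tight-capacity instance in which the
travel-optimal candidate set cannot serve demand, exposing the trade-off
between the conventional and the modified model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .config import CATEGORIES, ROAD_CATEGORIES
from .errors import GenerationError, InputError
from .metrics import DemandSite, aggregate_hospitals
from .network import Station, TransportSegment, polyline_length_km

__all__ = [
    "SyntheticInstance",
    "generate_instance",
    "worked_micro_instance",
    "tight_capacity_instance",
    "micro_optimum",
    "category_length_shares",
]

#: Henan-like defaults: bounding box (lon_min, lat_min, lon_max, lat_max),
#: category length shares and attribute ranges.
DEFAULT_BBOX = (110.4, 31.4, 116.6, 36.4)
# printed category percentages (42.1/13.0/31.1/10.5/2.3) sum to 99% after
# rounding; renormalized here so the shares form a proper composition
_RAW_SHARES = (0.421, 0.130, 0.311, 0.105, 0.023)
DEFAULT_SHARES = tuple(s / sum(_RAW_SHARES) for s in _RAW_SHARES)
DEFAULT_POP_RANGE = (1.5e6, 10.5e6)
DEFAULT_BEDS_RANGE = (600.0, 2600.0)


@dataclass
class SyntheticInstance:
    """A generated or hand-written location-allocation instance."""

    cities: list
    hospitals: pd.DataFrame
    facilities: list
    segments: list
    stations: list
    seed: int | None = None
    params: dict = field(default_factory=dict)


def category_length_shares(segments) -> dict[str, float]:
    """Realized share of total length per category."""
    lengths = {c: 0.0 for c in CATEGORIES}
    for s in segments:
        lengths[s.category] += s.length_km
    total = sum(lengths.values())
    if total <= 0:
        raise InputError("no segment length")
    return {c: length / total for c, length in lengths.items()}


def _blue_noise(rng, n, bbox, max_tries=20000):
    """Dart-throwing with a minimum separation scaled to the box area."""
    lon0, lat0, lon1, lat1 = bbox
    w, h = lon1 - lon0, lat1 - lat0
    r = 0.55 * (w * h / n) ** 0.5
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        x = lon0 + rng.random() * w
        y = lat0 + rng.random() * h
        if all((x - px) ** 2 + (y - py) ** 2 >= r * r for px, py in pts):
            pts.append((x, y))
        tries += 1
        if tries > max_tries:
            r *= 0.8  # relax separation rather than fail
            tries = 0
    return np.array(pts)


def _gabriel_edges(points: np.ndarray) -> list[tuple[int, int]]:
    """Gabriel graph: (u,v) is an edge iff the disk with diameter uv is empty.

    Contains the Euclidean MST, hence is connected.
    """
    n = len(points)
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    edges = []
    for u in range(n):
        mids = (points[u] + points[u + 1:]) / 2  # midpoints of (u, v>u)
        r2 = d2[u, u + 1:] / 4
        # distance from every other point w to each midpoint (closed disk:
        # points on the circle also block the edge)
        dm = np.sum((points[:, None, :] - mids[None, :, :]) ** 2, axis=-1)
        dm[u, :] = np.inf
        for j, v in enumerate(range(u + 1, n)):
            dm[v, j] = np.inf
        dmin = np.min(dm, axis=0)
        for k in np.nonzero(dmin > r2 + 1e-15)[0]:
            edges.append((u, u + 1 + int(k)))
    return edges


def _grid_edges(points: np.ndarray, rng) -> list[tuple[int, int]]:
    """Debug topology: connect each point to its 3 nearest neighbors (plus MST)."""
    from scipy.sparse.csgraph import minimum_spanning_tree
    from scipy.spatial.distance import squareform, pdist

    n = len(points)
    d = squareform(pdist(points))
    edges = set()
    for u in range(n):
        for v in np.argsort(d[u])[1:4]:
            edges.add((min(u, int(v)), max(u, int(v))))
    mst = minimum_spanning_tree(d).tocoo()
    for u, v in zip(mst.row, mst.col):
        edges.add((min(int(u), int(v)), max(int(u), int(v))))
    return sorted(edges)


def _assign_road_categories(rng, lengths, shares):
    """Greedy category labels approximating target length shares."""
    targets = np.asarray(shares, dtype=float)
    targets = targets / targets.sum()
    total = float(np.sum(lengths))
    assigned = np.zeros(len(targets))
    order = rng.permutation(len(lengths))
    labels = np.empty(len(lengths), dtype=int)
    for e in order:
        deficit = targets - assigned / total
        k = int(np.argmax(deficit))
        labels[e] = k
        assigned[k] += lengths[e]
    return labels


def _corridor(rng, cities_xy, city_order, offset):
    """Greedy nearest-neighbor tour through the given cities, offset in lat."""
    remaining = list(city_order)
    # start at the westernmost of the corridor cities
    start = min(remaining, key=lambda i: (cities_xy[i][0], cities_xy[i][1]))
    tour = [start]
    remaining.remove(start)
    while remaining:
        last = tour[-1]
        nxt = min(
            remaining,
            key=lambda i: (cities_xy[i][0] - cities_xy[last][0]) ** 2
            + (cities_xy[i][1] - cities_xy[last][1]) ** 2,
        )
        tour.append(nxt)
        remaining.remove(nxt)
    pts = [(cities_xy[i][0], cities_xy[i][1] + offset) for i in tour]
    return tour, pts


def generate_instance(
    n_cities: int = 17,
    n_hospitals: int = 38,
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX,
    category_shares: tuple[float, ...] = DEFAULT_SHARES,
    pop_range: tuple[float, float] = DEFAULT_POP_RANGE,
    beds_range: tuple[float, float] = DEFAULT_BEDS_RANGE,
    seed: int = 0,
    road_topology: str = "gabriel",
    n_waypoints: int | None = None,
    n_rail_cities: int = 6,
    n_hsr_cities: int = 4,
) -> SyntheticInstance:
    """Generate a seeded instance emulating the study-area structure."""
    if n_cities < 2:
        raise GenerationError("need at least 2 cities")
    shares = tuple(float(s) for s in category_shares)
    if len(shares) != 5 or any(s < 0 for s in shares):
        raise GenerationError("category_shares must be five non-negative values")
    if abs(sum(shares) - 1.0) > 1e-6:
        raise GenerationError("category_shares must sum to 1")
    rail_requested = shares[3] > 0 or shares[4] > 0
    if rail_requested and n_cities < 2:
        raise GenerationError("rail corridors need at least 2 cities")
    rng = np.random.default_rng(seed)

    city_xy = _blue_noise(rng, n_cities, bbox)
    lo, hi = pop_range
    pops = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cities))
    cities = [
        DemandSite(
            id=f"C{i + 1:02d}", name=f"city-{i + 1}",
            lon=float(city_xy[i, 0]), lat=float(city_xy[i, 1]),
            population=float(pops[i]),
        )
        for i in range(n_cities)
    ]

    # --- road network over cities + waypoints
    n_way = 2 * n_cities if n_waypoints is None else n_waypoints
    lon0, lat0, lon1, lat1 = bbox
    waypoints = np.column_stack(
        (
            rng.uniform(lon0, lon1, size=n_way),
            rng.uniform(lat0, lat1, size=n_way),
        )
    )
    points = np.vstack([city_xy, waypoints]) if n_way else city_xy
    if road_topology == "gabriel":
        edges = _gabriel_edges(points)
    elif road_topology == "grid":
        edges = _grid_edges(points, rng)
    else:
        raise GenerationError(f"unknown road topology {road_topology!r}")

    segments: list[TransportSegment] = []
    road_polys = []
    for u, v in edges:
        a, b = points[u], points[v]
        mid = (a + b) / 2 + rng.normal(0.0, 0.02, size=2)  # gentle road curvature
        road_polys.append([tuple(a), tuple(mid), tuple(b)])
    road_lengths = np.array([polyline_length_km(p) for p in road_polys])
    road_share_targets = np.asarray(shares[:3], dtype=float)
    if road_share_targets.sum() <= 0:
        raise GenerationError("road categories need positive total share")
    labels = _assign_road_categories(rng, road_lengths, road_share_targets)
    for k, (poly, lab) in enumerate(zip(road_polys, labels)):
        segments.append(
            TransportSegment(
                id=f"R{k + 1:04d}", polyline=tuple(poly),
                category=ROAD_CATEGORIES[lab],
            )
        )

    # --- rail corridors through the most populous cities
    stations: list[Station] = []
    pop_order = list(np.argsort(-pops))
    corridors = []
    if shares[3] > 0:
        corridors.append(("railway", pop_order[: max(2, n_rail_cities)], 0.035))
    if shares[4] > 0:
        corridors.append(
            ("high_speed_railway", pop_order[: max(2, n_hsr_cities)], -0.035)
        )
    seg_counter = 0
    for category, corridor_cities, offset in corridors:
        tour, pts = _corridor(rng, city_xy, corridor_cities, offset)
        for a, b in zip(pts[:-1], pts[1:]):
            seg_counter += 1
            segments.append(
                TransportSegment(
                    id=f"T{seg_counter:03d}", polyline=(a, b), category=category
                )
            )
        for ci, pt in zip(tour, pts):
            # station halfway between the city and its corridor node, so the
            # nearest rail segment is this corridor's
            stations.append(
                Station(
                    id=f"S-{category[:3]}-{cities[ci].id}",
                    lon=(cities[ci].lon + pt[0]) / 2,
                    lat=(cities[ci].lat + pt[1]) / 2,
                )
            )

    # --- hospitals: one per city first, the rest population-skewed
    if n_hospitals < 1:
        raise GenerationError("need at least one hospital")
    alloc = np.zeros(n_cities, dtype=int)
    if n_hospitals >= n_cities:
        alloc[:] = 1
        extra = n_hospitals - n_cities
    else:
        for i in pop_order[:n_hospitals]:
            alloc[i] = 1
        extra = 0
    if extra:
        w = pops**1.5
        alloc += rng.multinomial(extra, w / w.sum())
    rows = []
    hid = 0
    for i, count in enumerate(alloc):
        for _ in range(int(count)):
            hid += 1
            rows.append(
                {
                    "id": f"H{hid:03d}",
                    "city_id": cities[i].id,
                    "lon": cities[i].lon + rng.normal(0, 0.01),
                    "lat": cities[i].lat + rng.normal(0, 0.01),
                    "beds": float(
                        np.exp(rng.uniform(np.log(beds_range[0]), np.log(beds_range[1])))
                    ),
                    "ksd": int(rng.integers(1, 16)),
                    "ptr": float(rng.uniform(0.5, 3.5)),
                    "btr": float(rng.uniform(2.0, 9.0)),
                }
            )
    hospitals = pd.DataFrame(rows)
    facilities = aggregate_hospitals(hospitals, cities)

    return SyntheticInstance(
        cities=cities,
        hospitals=hospitals,
        facilities=facilities,
        segments=segments,
        stations=stations,
        seed=seed,
        params={
            "n_cities": n_cities,
            "n_hospitals": n_hospitals,
            "bbox": list(bbox),
            "category_shares": list(shares),
            "pop_range": list(pop_range),
            "beds_range": list(beds_range),
            "road_topology": road_topology,
            "n_rail_cities": n_rail_cities,
            "n_hsr_cities": n_hsr_cities,
        },
    )


# ---------------------------------------------------------------------------
# fixed instances

_MICRO_CITIES = [
    # id, lon, lat, population
    ("M1", 112.20, 33.60, 2_400_000.0),
    ("M2", 112.95, 34.15, 5_100_000.0),
    ("M3", 113.70, 33.95, 3_200_000.0),
    ("M4", 114.35, 34.40, 6_800_000.0),
    ("M5", 114.90, 33.70, 2_900_000.0),
    ("M6", 113.30, 33.20, 4_300_000.0),
    ("M7", 114.10, 33.05, 3_600_000.0),
    ("M8", 112.60, 32.85, 1_800_000.0),
]

_MICRO_ROADS = [
    ("M1", "M2"), ("M2", "M3"), ("M3", "M4"), ("M4", "M5"),
    ("M5", "M7"), ("M7", "M6"), ("M6", "M8"), ("M8", "M1"),
    ("M2", "M6"), ("M3", "M6"), ("M3", "M7"), ("M4", "M7"),
    ("M1", "M6"), ("M5", "M4"),
]

_MICRO_HOSPITALS = [
    # id, city, beds, ksd, ptr, btr
    ("HM1", "M2", 4000.0, 12, 2.8, 6.1),
    ("HM2", "M7", 3500.0, 7, 3.4, 4.9),
]

#: Compactness weighting factor used by the micro fixture.
MICRO_GAMMA = 1000.0


def worked_micro_instance() -> SyntheticInstance:
    """Fixed 8-city, 2-facility instance for exhaustive-oracle testing.

    Coordinates, populations and hospital attributes are hand-written; the
    road network is a hand-written planar graph of secondary ways. With two
    facilities and eight cities, all 2^8 = 256 assignments can be enumerated,
    and the frozen optimum is shipped alongside (see ``micro_optimum``).
    """
    cities = [
        DemandSite(id=i, name=i, lon=x, lat=y, population=p)
        for i, x, y, p in _MICRO_CITIES
    ]
    coord = {c.id: (c.lon, c.lat) for c in cities}
    segments = [
        TransportSegment(
            id=f"MR{k + 1:02d}",
            polyline=(coord[a], coord[b]),
            category="secondary",
        )
        for k, (a, b) in enumerate(_MICRO_ROADS)
    ]
    hospitals = pd.DataFrame(
        [
            {"id": h, "city_id": c, "lon": coord[c][0], "lat": coord[c][1],
             "beds": beds, "ksd": ksd, "ptr": ptr, "btr": btr}
            for h, c, beds, ksd, ptr, btr in _MICRO_HOSPITALS
        ]
    )
    facilities = aggregate_hospitals(hospitals, cities)
    return SyntheticInstance(
        cities=cities,
        hospitals=hospitals,
        facilities=facilities,
        segments=segments,
        stations=[],
        seed=None,
        params={"fixture": "micro", "gamma": MICRO_GAMMA},
    )


def micro_optimum() -> dict:
    """Frozen exhaustive optimum of the micro instance.

    Produced by enumerating all 256 assignments of the micro instance with
    the package's scoring (gamma and multipliers recorded in the file); used
    as the reference the annealer must attain.
    """
    with resources.files("medloc.data").joinpath("micro_optimum.json").open() as fh:
        return json.load(fh)


_TIGHT_CITIES = [
    # western ladder: two columns of high-demand cities
    ("W1", 112.60, 34.80, 6_000_000.0),
    ("W2", 113.00, 34.78, 5_800_000.0),
    ("W3", 112.62, 34.30, 6_400_000.0),
    ("W4", 113.02, 34.32, 6_100_000.0),
    ("W5", 112.58, 33.80, 6_200_000.0),
    ("W6", 112.98, 33.78, 5_900_000.0),
    ("W7", 112.64, 33.30, 6_000_000.0),
    ("W8", 113.04, 33.32, 5_700_000.0),
    # central column: big hospital city flanked by two small candidates
    ("CC", 112.80, 34.05, 6_300_000.0),
    ("CA", 112.78, 34.40, 5_600_000.0),
    ("CB", 112.82, 33.70, 5_500_000.0),
    # eastern low-demand cluster across a sparse gap
    ("E1", 115.10, 34.45, 1_300_000.0),
    ("E2", 115.30, 34.25, 1_200_000.0),
    ("E3", 115.05, 34.05, 1_400_000.0),
    ("E4", 115.28, 33.85, 1_200_000.0),
    ("E5", 115.12, 33.65, 1_300_000.0),
]

_TIGHT_HOSPITALS = [
    # the travel-optimal pair {CA, CB}: well placed, too few beds
    ("HA", "CA", 1300.0, 12, 3.0, 6.0),
    ("HB", "CB", 1300.0, 11, 2.8, 5.5),
    # capacious alternatives: the central hub and the eastern center
    ("HC", "CC", 18000.0, 9, 2.2, 7.5),
    ("HE", "E3", 2800.0, 8, 2.0, 7.0),
]

#: Parameters the tight-capacity demonstration runs with: deficits persist
#: (no capacity augmentation) so the capacity term truly binds.
TIGHT_GAMMA = 600.0
TIGHT_INCREASING_FACTOR = 0.0


def tight_capacity_instance() -> SyntheticInstance:
    """Fixed instance where the travel-optimal set cannot serve demand.

    The two small central candidates (CA, CB) minimize travel over the
    high-demand western ladder, but their beds cover only a fraction of
    total demand and their closest-assignment split slices through the
    dense ladder and the eastern cluster. The capacious pair (CC, E3)
    serves everything within capacity and splits the plane along the
    sparse gap. Run with no capacity augmentation (increasing factor 0),
    this exposes the trade-off between the conventional and the modified
    model: lower capacity and spatial cost at a higher travel cost.
    """
    cities = [
        DemandSite(id=i, name=i, lon=x, lat=y, population=p)
        for i, x, y, p in _TIGHT_CITIES
    ]
    coord = {c.id: (c.lon, c.lat) for c in cities}
    xy = np.array([[c.lon, c.lat] for c in cities])
    segments = [
        TransportSegment(
            id=f"TR{k + 1:02d}",
            polyline=(tuple(xy[u]), tuple(xy[v])),
            category="secondary",
        )
        for k, (u, v) in enumerate(_gabriel_edges(xy))
    ]
    hospitals = pd.DataFrame(
        [
            {"id": h, "city_id": c, "lon": coord[c][0], "lat": coord[c][1],
             "beds": beds, "ksd": ksd, "ptr": ptr, "btr": btr}
            for h, c, beds, ksd, ptr, btr in _TIGHT_HOSPITALS
        ]
    )
    facilities = aggregate_hospitals(hospitals, cities)
    return SyntheticInstance(
        cities=cities,
        hospitals=hospitals,
        facilities=facilities,
        segments=segments,
        stations=[],
        seed=None,
        params={
            "fixture": "tight_capacity",
            "gamma": TIGHT_GAMMA,
            "increasing_factor": TIGHT_INCREASING_FACTOR,
        },
    )
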