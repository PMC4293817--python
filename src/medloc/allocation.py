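"""Demand allocation by simulated annealing.

Given a candidate set of P facilities, demand sites are assigned to
facilities so as to minimize a three-term objective:

* **travel cost** — demand-weighted travel time summed over all sites;
* **capacity cost** — the sum over facilities of the shortage ratio,
  ``max(0, (allocated - capacity) / capacity)``, penalizing overload;
* **spatial cost** — ``-gamma`` times, for each site, the number of its
  Voronoi-neighboring sites assigned to the same facility; a negative
  reward for spatially compact service areas that discourages crossing
  supply lines.

The annealer starts from a random feasible assignment and proposes local
moves in which a site adopts the facility of a Voronoi neighbor, accepting
uphill moves by the Metropolis criterion under a geometric cooling
schedule. Every demand site is assigned to exactly one facility of the set
at all times, so the P-median feasibility constraints hold throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from . import _engine
from .errors import InputError, ScheduleError
from .network import TravelTimeMatrix
from .siting import CandidateSet

__all__ = [
    "Assignment",
    "VoronoiAdjacency",
    "CostBreakdown",
    "AnnealingSchedule",
    "Solution",
    "voronoi_adjacency",
    "travel_cost",
    "shortage_ratio",
    "spatial_cost",
    "total_cost",
    "metropolis_accept",
    "propose_move",
    "score_assignment",
    "closest_assignment",
    "exhaustive_best_assignment",
    "anneal",
]

#: An assignment maps each demand-site id to the id of its serving facility.
Assignment = dict


@dataclass
class VoronoiAdjacency:
    """Symmetric neighbor relation over demand sites (shared Voronoi edges)."""

    site_ids: list
    neighbors: dict

    def __post_init__(self) -> None:
        for i, nbrs in self.neighbors.items():
            if i in nbrs:
                raise InputError("adjacency must be irreflexive")
            for k in nbrs:
                if i not in self.neighbors.get(k, ()):
                    raise InputError("adjacency must be symmetric")

    @property
    def edges(self) -> set:
        out = set()
        for i, nbrs in self.neighbors.items():
            for k in nbrs:
                out.add(frozenset((i, k)))
        return out

    def csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR arrays over site indices in ``site_ids`` order."""
        index = {s: i for i, s in enumerate(self.site_ids)}
        indptr = [0]
        indices = []
        for s in self.site_ids:
            nbrs = sorted(self.neighbors[s], key=lambda x: index[x])
            indices.extend(index[k] for k in nbrs)
            indptr.append(len(indices))
        return np.asarray(indptr, dtype=np.int64), np.asarray(indices, dtype=np.int64)


def equirectangular_xy(coords: np.ndarray) -> np.ndarray:
    """Project lon/lat (degrees) to planar km about the instance centroid."""
    coords = np.asarray(coords, dtype=float)
    lon0, lat0 = coords.mean(axis=0)
    kx = 111.32 * math.cos(math.radians(lat0))
    ky = 111.32
    return np.column_stack(((coords[:, 0] - lon0) * kx, (coords[:, 1] - lat0) * ky))


def voronoi_adjacency(coords, site_ids=None) -> VoronoiAdjacency:
    """Neighbor relation of sites whose Voronoi cells share an edge.

    Equivalent to Delaunay connectivity, computed on an equirectangular
    projection of the lon/lat coordinates. Collinear site sets (where the
    triangulation is degenerate) fall back to chain adjacency along the
    line; two sites are always neighbors.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise InputError("voronoi_adjacency requires at least 2 sites")
    if site_ids is None:
        site_ids = list(range(n))
    if len(np.unique(coords, axis=0)) != n:
        raise InputError("duplicate site coordinates")
    xy = equirectangular_xy(coords)
    neighbors = {s: set() for s in site_ids}

    def chain_fallback():
        # order along the dominant axis of the (collinear) point cloud
        c = xy - xy.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        order = np.argsort(c @ vt[0])
        for a, b in zip(order[:-1], order[1:]):
            neighbors[site_ids[a]].add(site_ids[b])
            neighbors[site_ids[b]].add(site_ids[a])

    if n == 2:
        neighbors[site_ids[0]].add(site_ids[1])
        neighbors[site_ids[1]].add(site_ids[0])
    else:
        try:
            tri = Delaunay(xy)
            if tri.simplices.size == 0:
                chain_fallback()
            else:
                for simplex in tri.simplices:
                    for a in simplex:
                        for b in simplex:
                            if a != b:
                                neighbors[site_ids[a]].add(site_ids[b])
        except QhullError:
            chain_fallback()
    return VoronoiAdjacency(site_ids=list(site_ids), neighbors=neighbors)


@dataclass
class CostBreakdown:
    """The objective value and its components for one assignment."""

    travel: float
    capacity: float
    spatial: float
    total: float
    multipliers: tuple[float, float]
    shortage_ratios: dict = field(default_factory=dict)
    spatial_terms: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "travel_cost": self.travel,
            "capacity_cost": self.capacity,
            "spatial_cost": self.spatial,
            "total_cost": self.total,
        }


@dataclass
class AnnealingSchedule:
    """Geometric cooling schedule.

    ``t0=None`` requests the adaptive default: twice the standard deviation
    of the objective change over 100 random moves from the initial state.
    ``iterations_per_temperature=None`` defaults to 100 times the number of
    demand sites; ``t_min=None`` defaults to ``1e-3 * t0``.
    """

    t0: float | None = None
    cooling_factor: float = 0.95
    iterations_per_temperature: int | None = None
    t_min: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cooling_factor < 1):
            raise ScheduleError("cooling_factor must lie in (0, 1)")
        if self.t0 is not None and self.t0 <= 0:
            raise ScheduleError("t0 must be positive")
        if self.t_min is not None and self.t_min <= 0:
            raise ScheduleError("t_min must be positive")
        if (
            self.t0 is not None
            and self.t_min is not None
            and not self.t0 > self.t_min
        ):
            raise ScheduleError("t0 must exceed t_min")
        if (
            self.iterations_per_temperature is not None
            and self.iterations_per_temperature < 1
        ):
            raise ScheduleError("iterations_per_temperature must be >= 1")

    def temperatures(self, t0: float, t_min: float) -> np.ndarray:
        temps = []
        t = t0
        while t > t_min:
            temps.append(t)
            t *= self.cooling_factor
        if not temps:
            temps = [t0]
        return np.asarray(temps)


@dataclass
class Solution:
    """Best assignment found for one candidate set, with costs and trace."""

    candidate_set: CandidateSet
    assignment: Assignment
    costs: CostBreakdown
    seed: int
    trace: dict = field(default_factory=dict)
    gamma: float = 0.0


def _time_lookup(times):
    if isinstance(times, TravelTimeMatrix):
        oi = {o: i for i, o in enumerate(times.origins)}
        dj = {d: j for j, d in enumerate(times.destinations)}
        arr = times.times

        def look(i, j):
            try:
                return float(arr[oi[i], dj[j]])
            except KeyError:
                raise InputError(f"no travel time entry for pair ({i!r}, {j!r})")

        return look

    def look(i, j):
        try:
            return float(times[(i, j)])
        except KeyError:
            raise InputError(f"no travel time entry for pair ({i!r}, {j!r})")

    return look


def travel_cost(assignment: Assignment, demands: dict, times) -> float:
    """Demand-weighted travel time: sum_i demand_i * t(i, assignment(i))."""
    look = _time_lookup(times)
    return float(sum(demands[i] * look(i, j) for i, j in assignment.items()))


def shortage_ratio(capacity: float, allocated: float) -> float:
    """Unmet-demand fraction ``max(0, (allocated - capacity) / capacity)``.

    Zero means the facility satisfies all allocated demand with its current
    capacity; surplus capacity is not rewarded.
    """
    if capacity <= 0:
        raise InputError("capacity must be positive")
    if allocated < 0:
        raise InputError("allocated demand must be non-negative")
    return max(0.0, (allocated - capacity) / capacity)


def spatial_cost(
    assignment: Assignment, adjacency: VoronoiAdjacency, gamma: float
) -> tuple[float, dict]:
    """Compactness reward: per site, ``-gamma`` times same-assigned neighbors.

    Returns (total, per-site terms). Each adjacency is counted from both of
    its endpoints, so the total equals ``-gamma * 2 *`` (number of
    monochromatic Delaunay edges).
    """
    if gamma < 0:
        raise InputError("gamma must be non-negative")
    terms = {}
    for i in adjacency.site_ids:
        same = sum(1 for k in adjacency.neighbors[i] if assignment[k] == assignment[i])
        terms[i] = -gamma * same
    return float(sum(terms.values())), terms


def total_cost(
    travel: float,
    capacity: float,
    spatial: float,
    multipliers: tuple[float, float] = (1.0, 1.0),
) -> CostBreakdown:
    """Combine the three components: total = travel + l_cap*capacity + l_sp*spatial."""
    lam_cap, lam_sp = multipliers
    if lam_cap < 0 or lam_sp < 0:
        raise InputError("multipliers must be non-negative")
    return CostBreakdown(
        travel=float(travel),
        capacity=float(capacity),
        spatial=float(spatial),
        total=float(travel + lam_cap * capacity + lam_sp * spatial),
        multipliers=(float(lam_cap), float(lam_sp)),
    )


def metropolis_accept(delta: float, t: float, u: float) -> bool:
    """Metropolis criterion: accept iff delta <= 0, else iff u < exp(-delta/t)."""
    if t <= 0:
        raise ScheduleError("temperature must be positive")
    if delta <= 0:
        return True
    return u < math.exp(-delta / t)


def propose_move(assignment: Assignment, adjacency: VoronoiAdjacency, facilities, rng):
    """One neighborhood move: a site adopts a Voronoi neighbor's facility.

    Picks a uniformly random site among those with at least one
    differently-assigned neighbor (equivalent to resampling a uniformly
    random site until one qualifies), then a uniformly random such neighbor,
    and propagates that neighbor's facility to the site. When every site
    shares one facility, the site is reassigned to a uniformly random other
    facility of the set. Returns ``(new_assignment, changed)``; ``changed``
    is False only for a single-facility set, whose move is the identity.
    """
    facilities = list(facilities)
    if len(facilities) < 2:
        return dict(assignment), False
    eligible = [
        i
        for i in adjacency.site_ids
        if any(assignment[k] != assignment[i] for k in adjacency.neighbors[i])
    ]
    new = dict(assignment)
    if eligible:
        i = eligible[int(rng.random() * len(eligible))]
        # choose among differently-assigned neighbors, then adopt
        nbrs = [k for k in sorted(adjacency.neighbors[i], key=str)
                if assignment[k] != assignment[i]]
        k = nbrs[int(rng.random() * len(nbrs))]
        new[i] = assignment[k]
    else:
        sites = adjacency.site_ids
        i = sites[int(rng.random() * len(sites))]
        others = [f for f in facilities if f != assignment[i]]
        new[i] = others[int(rng.random() * len(others))]
    return new, True


def score_assignment(
    assignment: Assignment,
    demands: dict,
    times,
    capacities: dict,
    adjacency: VoronoiAdjacency,
    gamma: float,
    multipliers: tuple[float, float],
    weighted_travel: bool = True,
) -> CostBreakdown:
    """Full cost breakdown of an assignment (used for scoring and re-scoring)."""
    look = _time_lookup(times)
    if weighted_travel:
        travel = sum(demands[i] * look(i, j) for i, j in assignment.items())
    else:
        travel = sum(look(i, j) for i, j in assignment.items())
    loads = {j: 0.0 for j in capacities}
    for i, j in assignment.items():
        if j not in loads:
            raise InputError(f"assignment targets facility {j!r} outside the set")
        loads[j] += demands[i]
    ratios = {j: shortage_ratio(capacities[j], loads[j]) for j in capacities}
    cap = sum(ratios.values())
    spat, terms = spatial_cost(assignment, adjacency, gamma)
    breakdown = total_cost(travel, cap, spat, multipliers)
    breakdown.shortage_ratios = ratios
    breakdown.spatial_terms = terms
    return breakdown


def closest_assignment(times, site_ids, facility_ids) -> Assignment:
    """Conventional P-median allocation: each site to its closest facility.

    Ties are broken toward the lexicographically smallest facility id.
    """
    look = _time_lookup(times)
    out = {}
    for i in site_ids:
        out[i] = min(facility_ids, key=lambda j: (look(i, j), str(j)))
    return out


def exhaustive_best_assignment(
    site_ids,
    facility_ids,
    demands,
    times,
    capacities,
    adjacency,
    gamma,
    multipliers,
    weighted_travel=True,
):
    """Global optimum by enumerating all p^n assignments (tiny instances only)."""
    n = len(site_ids)
    p = len(facility_ids)
    if p**n > 2_000_000:
        raise InputError("instance too large for exhaustive enumeration")
    best = None
    best_cost = math.inf
    for code in range(p**n):
        c = code
        assignment = {}
        for i in site_ids:
            assignment[i] = facility_ids[c % p]
            c //= p
        b = score_assignment(
            assignment, demands, times, capacities, adjacency, gamma,
            multipliers, weighted_travel,
        )
        if b.total < best_cost - 1e-12:
            best_cost = b.total
            best = (assignment, b)
    return best


def _default_t0(
    assignment, adjacency, facilities, demands, times, capacities,
    gamma, multipliers, weighted_travel, rng, n_probe=100,
):
    """Adaptive initial temperature: 2 * std of the cost change over random moves."""
    cur = dict(assignment)
    cur_cost = score_assignment(
        cur, demands, times, capacities, adjacency, gamma, multipliers, weighted_travel
    ).total
    deltas = []
    for _ in range(n_probe):
        nxt, changed = propose_move(cur, adjacency, facilities, rng)
        if not changed:
            break
        nxt_cost = score_assignment(
            nxt, demands, times, capacities, adjacency, gamma, multipliers,
            weighted_travel,
        ).total
        deltas.append(nxt_cost - cur_cost)
        cur, cur_cost = nxt, nxt_cost  # random walk samples diverse states
    sd = float(np.std(deltas)) if deltas else 0.0
    return 2.0 * sd if sd > 0 else 1.0


def anneal(
    candidate_set: CandidateSet,
    demands: dict,
    times,
    adjacency: VoronoiAdjacency,
    gamma: float,
    multipliers: tuple[float, float],
    schedule: AnnealingSchedule | None = None,
    *,
    weighted_travel: bool = True,
    engine: str = "auto",
    validate: bool = False,
) -> Solution:
    """Simulated-annealing allocation for one candidate set.

    Starts from a random feasible assignment, runs the full cooling
    schedule and returns the best-so-far assignment with its cost
    breakdown and a per-temperature trace. Fully reproducible from
    ``schedule.seed``. ``engine`` is ``"auto"`` (numba when available),
    ``"numba"`` or ``"python"``; all engines give identical results.
    """
    schedule = schedule or AnnealingSchedule()
    site_ids = list(adjacency.site_ids)
    fac_ids = list(candidate_set.facilities)
    n, p = len(site_ids), len(fac_ids)
    capacities = dict(zip(fac_ids, candidate_set.augmented_capacities))
    rng = np.random.default_rng(schedule.seed)

    if p == 1:
        assignment = {i: fac_ids[0] for i in site_ids}
        costs = score_assignment(
            assignment, demands, times, capacities, adjacency, gamma,
            multipliers, weighted_travel,
        )
        return Solution(
            candidate_set=candidate_set, assignment=assignment, costs=costs,
            seed=schedule.seed, gamma=gamma,
            trace={"temperature": np.empty(0), "current_cost": np.empty(0),
                   "best_cost": np.empty(0)},
        )

    assign0 = rng.integers(0, p, size=n)
    assignment0 = {i: fac_ids[a] for i, a in zip(site_ids, assign0)}

    t0 = schedule.t0
    if t0 is None:
        t0 = _default_t0(
            assignment0, adjacency, fac_ids, demands, times, capacities,
            gamma, multipliers, weighted_travel, rng,
        )
    t_min = schedule.t_min if schedule.t_min is not None else 1e-3 * t0
    if not t0 > t_min:
        raise ScheduleError("t0 must exceed t_min")
    L = schedule.iterations_per_temperature or 100 * n
    temps = schedule.temperatures(t0, t_min)

    look = _time_lookup(times)
    times_arr = np.array(
        [[look(i, j) for j in fac_ids] for i in site_ids], dtype=float
    )
    dem_arr = np.array([demands[i] for i in site_ids], dtype=float)
    tweights = dem_arr if weighted_travel else np.ones(n)
    caps_arr = np.array([capacities[j] for j in fac_ids], dtype=float)
    indptr, indices = adjacency.csr()
    lam_cap, lam_sp = multipliers

    step = _engine.sa_step_python
    if engine == "auto":
        step = _engine.sa_step_jit or _engine.sa_step_python
    elif engine == "numba":
        if _engine.sa_step_jit is None:
            raise ScheduleError("numba engine requested but numba is unavailable")
        step = _engine.sa_step_jit
    elif engine != "python":
        raise InputError(f"unknown engine {engine!r}")

    rand = rng.random((len(temps) * L, 3))
    assign = assign0.astype(np.int64).copy()
    best_assign = assign.copy()
    best = math.inf
    trace_t = np.asarray(temps)
    trace_cur = np.empty(len(temps))
    trace_best = np.empty(len(temps))
    for s, t in enumerate(temps):
        best, cur, _ = step(
            times_arr, tweights, dem_arr, caps_arr, indptr, indices,
            float(gamma), float(lam_cap), float(lam_sp),
            assign, best_assign, best, float(t),
            rand[s * L:(s + 1) * L],
        )
        trace_cur[s] = cur
        trace_best[s] = best
        if validate:
            if not np.all((assign >= 0) & (assign < p)):
                raise InputError("internal: infeasible assignment during annealing")

    best_assignment = {i: fac_ids[a] for i, a in zip(site_ids, best_assign)}
    costs = score_assignment(
        best_assignment, demands, times, capacities, adjacency, gamma,
        multipliers, weighted_travel,
    )
    return Solution(
        candidate_set=candidate_set,
        assignment=best_assignment,
        costs=costs,
        seed=schedule.seed,
        gamma=gamma,
        trace={
            "temperature": trace_t,
            "current_cost": trace_cur,
            "best_cost": trace_best,
        },
    )
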