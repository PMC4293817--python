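"""Full pipeline: evaluate every candidate set and build the solution table.

Each candidate set of P facilities is augmented (if needed) and allocated by
simulated annealing; one row per set records the five decision variables —
total cost, travel cost, capacity cost, spatial cost and capacity
investment — forming the table a parallel-coordinate / geomap tool ingests
for visual-analytic selection. The final choice among near-tied solutions is
deliberately left to decision makers; this module only computes, ranks and
exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allocation import (
    AnnealingSchedule,
    Solution,
    VoronoiAdjacency,
    anneal,
    closest_assignment,
    score_assignment,
    travel_cost,
    voronoi_adjacency,
)
from .config import ModelConfig
from .errors import InputError
from .metrics import attractiveness as compute_attractiveness
from .metrics import center_capacity, city_demand
from .network import (
    TransportGraph,
    TravelTimeMatrix,
    build_graph,
    shortest_time_matrix,
    snap_to_network,
)
from .siting import augment_capacities, enumerate_candidate_sets

__all__ = [
    "Problem",
    "SolutionTable",
    "evaluate_all",
    "rank_solutions",
    "gamma_sweep",
    "compare_models",
    "rescore",
    "default_lambda_capacity",
]

RANKABLE = (
    "total_cost",
    "travel_cost",
    "capacity_cost",
    "spatial_cost",
    "capacity_investment",
)


@dataclass
class Problem:
    """A fully prepared location-allocation problem.

    Holds the demand sites, candidate facilities (with capacity and
    attractiveness computed), the shortest-travel-time matrix between them
    and the Voronoi adjacency of the demand sites.
    """

    site_ids: list
    facility_ids: list
    demands: dict
    capacities: dict
    attractiveness: dict
    times: TravelTimeMatrix
    adjacency: VoronoiAdjacency
    config: ModelConfig = field(default_factory=ModelConfig)
    graph: TransportGraph | None = None

    @property
    def total_demand(self) -> float:
        return float(sum(self.demands.values()))

    @classmethod
    def from_instance(cls, instance, config: ModelConfig | None = None) -> "Problem":
        """Build a problem from a SyntheticInstance (or any object with
        ``cities``, ``facilities``, ``segments``, ``stations`` attributes)."""
        config = config or ModelConfig()
        graph = build_graph(
            instance.segments,
            instance.stations,
            speed_table=config.speed_table,
            snap_tolerance=config.snap_tolerance,
            transfer_penalty_hours=config.transfer_penalty_hours,
        )
        demands = {}
        for c in instance.cities:
            c.demand = city_demand(c.population, config.alpha, config.theta)
            demands[c.id] = c.demand
        for f in instance.facilities:
            f.capacity = center_capacity(f.beds, config.alos, config.horizon_days)
        attr = compute_attractiveness(instance.facilities, config.weights)
        site_nodes = [snap_to_network(graph, (c.lon, c.lat)) for c in instance.cities]
        fac_nodes = [snap_to_network(graph, (f.lon, f.lat)) for f in instance.facilities]
        node_times = shortest_time_matrix(graph, site_nodes, fac_nodes)
        times = TravelTimeMatrix(
            origins=[c.id for c in instance.cities],
            destinations=[f.id for f in instance.facilities],
            times=node_times.times,
        )
        adjacency = voronoi_adjacency(
            np.array([[c.lon, c.lat] for c in instance.cities]),
            site_ids=[c.id for c in instance.cities],
        )
        return cls(
            site_ids=[c.id for c in instance.cities],
            facility_ids=[f.id for f in instance.facilities],
            demands=demands,
            capacities={f.id: f.capacity for f in instance.facilities},
            attractiveness=attr,
            times=times,
            adjacency=adjacency,
            config=config,
            graph=graph,
        )

    def multipliers(self) -> tuple[float, float]:
        lam_cap = self.config.lambda_capacity
        if lam_cap is None:
            lam_cap = default_lambda_capacity(self)
        return (float(lam_cap), float(self.config.lambda_spatial))


def default_lambda_capacity(problem: Problem) -> float:
    """Instance-scaled capacity multiplier.

    One unit of shortage ratio is made commensurable with travel cost by
    valuing it at the median city's travel cost: the median over demand
    sites of ``demand_i * (median travel time to the candidate facilities)``.
    The median (not minimum) travel time is used because candidate
    facilities are typically co-located with cities, which would make the
    nearest time identically zero.
    """
    look = problem.times
    per_site = []
    for i_idx, i in enumerate(problem.site_ids):
        t_med = float(np.median(look.times[i_idx, :]))
        per_site.append(problem.demands[i] * t_med)
    med = float(np.median(per_site))
    return med if med > 0 else 1.0


@dataclass
class SolutionTable:
    """One row per candidate set plus the underlying Solution objects."""

    table: pd.DataFrame
    solutions: dict
    master_seed: int
    gamma: float
    multipliers: tuple[float, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def row(self, set_id: str) -> pd.Series:
        match = self.table[self.table["set_id"] == set_id]
        if match.empty:
            raise InputError(f"no candidate set {set_id!r} in the table")
        return match.iloc[0]

    def best(self, key: str = "total_cost") -> Solution:
        ranked = rank_solutions(self, key)
        return self.solutions[ranked.iloc[0]["set_id"]]


def _per_set_seed(master_seed: int, set_index: int) -> int:
    """Stable per-set seed so each set is independently reproducible."""
    ss = np.random.SeedSequence([int(master_seed), int(set_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_all(
    problem: Problem,
    p: int,
    gamma: float | None = None,
    multipliers: tuple[float, float] | None = None,
    schedule: AnnealingSchedule | None = None,
    n_restarts: int = 1,
    master_seed: int = 0,
    engine: str = "auto",
) -> SolutionTable:
    """Anneal every candidate set and assemble the solution table.

    Each set is annealed ``n_restarts`` times with seeds derived from the
    master seed; the best run is kept. Deterministic for a fixed master seed.
    """
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    gamma = problem.config.gamma if gamma is None else gamma
    multipliers = problem.multipliers() if multipliers is None else multipliers
    schedule = schedule or AnnealingSchedule()
    csets = enumerate_candidate_sets(problem.facility_ids, p, problem.capacities)
    total_demand = problem.total_demand
    rows = []
    solutions: dict[str, Solution] = {}
    for idx, cset in enumerate(csets):
        cset = augment_capacities(
            cset,
            total_demand,
            problem.config.increasing_factor,
            problem.attractiveness,
        )
        best_sol = None
        for r in range(n_restarts):
            seed = _per_set_seed(master_seed, idx * 10_000 + r)
            sched = AnnealingSchedule(
                t0=schedule.t0,
                cooling_factor=schedule.cooling_factor,
                iterations_per_temperature=schedule.iterations_per_temperature,
                t_min=schedule.t_min,
                seed=seed,
            )
            try:
                sol = anneal(
                    cset,
                    problem.demands,
                    problem.times,
                    problem.adjacency,
                    gamma,
                    multipliers,
                    sched,
                    weighted_travel=problem.config.weighted_travel,
                    engine=engine,
                )
            except Exception as exc:
                raise type(exc)(f"candidate set {cset.id}: {exc}") from exc
            if best_sol is None or sol.costs.total < best_sol.costs.total:
                best_sol = sol
        solutions[cset.id] = best_sol
        rows.append(
            {
                "set_id": cset.id,
                "members": ",".join(str(f) for f in cset.facilities),
                "total_cost": best_sol.costs.total,
                "travel_cost": best_sol.costs.travel,
                "capacity_cost": best_sol.costs.capacity,
                "spatial_cost": best_sol.costs.spatial,
                "capacity_investment": cset.capacity_investment,
                "seed": best_sol.seed,
            }
        )
    table = pd.DataFrame(rows)
    for key in RANKABLE:
        order = table.sort_values(
            [key, "set_id"], kind="stable"
        ).index
        rank = pd.Series(range(1, len(table) + 1), index=order)
        table[f"rank_{key}"] = rank
    return SolutionTable(
        table=table,
        solutions=solutions,
        master_seed=master_seed,
        gamma=gamma,
        multipliers=multipliers,
    )


def rank_solutions(table: SolutionTable, key: str) -> pd.DataFrame:
    """Stable ascending sort of the table by one of the five variables.

    Ascending order puts the most negative spatial cost first; ties are
    broken by lexicographic member ids.
    """
    if key not in RANKABLE:
        raise InputError(f"unknown ranking key {key!r}; choose one of {RANKABLE}")
    return table.table.sort_values(
        [key, "set_id"], kind="stable"
    ).reset_index(drop=True)


def gamma_sweep(
    problem: Problem,
    p: int,
    gammas,
    multipliers: tuple[float, float] | None = None,
    schedule: AnnealingSchedule | None = None,
    n_restarts: int = 1,
    master_seed: int = 0,
    engine: str = "auto",
) -> dict:
    """Evaluate the pipeline for each gamma; report the min-spatial-cost solution.

    Supports the visual selection of the compactness weighting factor: for
    each gamma the full solution table and the solution with minimum spatial
    cost (total cost as tie-break) are returned.
    """
    gammas = list(gammas)
    if not gammas:
        raise InputError("gamma_sweep needs at least one gamma value")
    out = {}
    for g in gammas:
        table = evaluate_all(
            problem, p, gamma=g, multipliers=multipliers, schedule=schedule,
            n_restarts=n_restarts, master_seed=master_seed, engine=engine,
        )
        ranked = table.table.sort_values(
            ["spatial_cost", "total_cost", "set_id"], kind="stable"
        )
        best = table.solutions[ranked.iloc[0]["set_id"]]
        out[g] = {"table": table, "best_spatial": best}
    return out


def _five_variables(problem, cset, assignment, gamma, multipliers):
    costs = score_assignment(
        assignment,
        problem.demands,
        problem.times,
        dict(zip(cset.facilities, cset.augmented_capacities)),
        problem.adjacency,
        gamma,
        multipliers,
        problem.config.weighted_travel,
    )
    return {
        "members": ",".join(str(f) for f in cset.facilities),
        "total_cost": costs.total,
        "travel_cost": costs.travel,
        "capacity_cost": costs.capacity,
        "spatial_cost": costs.spatial,
        "capacity_investment": cset.capacity_investment,
    }


def compare_models(
    problem: Problem,
    p: int,
    gamma: float | None = None,
    multipliers: tuple[float, float] | None = None,
    schedule: AnnealingSchedule | None = None,
    n_restarts: int = 1,
    master_seed: int = 0,
    engine: str = "auto",
) -> pd.DataFrame:
    """Conventional closest-assignment P-median vs the modified model.

    The conventional solution picks, over all candidate sets, the set whose
    closest-facility allocation minimizes demand-weighted travel time (the
    classical objective). The modified solution is the minimum-total-cost
    row of the annealed solution table. Both are reported with all five
    decision variables, scored identically, so the capacity / spatial /
    travel trade-off between the two models is directly visible.
    """
    gamma = problem.config.gamma if gamma is None else gamma
    multipliers = problem.multipliers() if multipliers is None else multipliers
    total_demand = problem.total_demand
    csets = [
        augment_capacities(
            c, total_demand, problem.config.increasing_factor, problem.attractiveness
        )
        for c in enumerate_candidate_sets(problem.facility_ids, p, problem.capacities)
    ]
    conv_best = None
    for cset in csets:
        assignment = closest_assignment(
            problem.times, problem.site_ids, list(cset.facilities)
        )
        tc = travel_cost(assignment, problem.demands, problem.times)
        key = (tc, cset.id)
        if conv_best is None or key < conv_best[0]:
            conv_best = (key, cset, assignment)
    _, conv_set, conv_assignment = conv_best

    table = evaluate_all(
        problem, p, gamma=gamma, multipliers=multipliers, schedule=schedule,
        n_restarts=n_restarts, master_seed=master_seed, engine=engine,
    )
    mod_sol = table.best("total_cost")

    rows = [
        {
            "model": "conventional",
            **_five_variables(problem, conv_set, conv_assignment, gamma, multipliers),
        },
        {
            "model": "modified",
            **_five_variables(
                problem, mod_sol.candidate_set, mod_sol.assignment, gamma, multipliers
            ),
        },
    ]
    return pd.DataFrame(rows)


def rescore(problem: Problem, solution: Solution, gamma: float | None = None,
            multipliers: tuple[float, float] | None = None):
    """Re-score a solution's stored assignment from scratch (round-trip check)."""
    gamma = solution.gamma if gamma is None else gamma
    multipliers = solution.costs.multipliers if multipliers is None else multipliers
    cset = solution.candidate_set
    return score_assignment(
        solution.assignment,
        problem.demands,
        problem.times,
        dict(zip(cset.facilities, cset.augmented_capacities)),
        problem.adjacency,
        gamma,
        multipliers,
        problem.config.weighted_travel,
    )
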