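import math

import numpy as np
import pytest

import medloc as m
from medloc.errors import InputError, ScheduleError

from conftest import oracle_exhaustive_minimum


class TestVoronoiAdjacency:
    def test_triangle_all_pairs_adjacent(self):
        adj = m.voronoi_adjacency([(0, 0), (1, 0), (0.4, 1)], ["a", "b", "c"])
        assert adj.edges == {frozenset(p) for p in (("a", "b"), ("a", "c"), ("b", "c"))}

    def test_unit_square_has_five_edges(self):
        adj = m.voronoi_adjacency([(0, 0), (1, 0), (1, 1), (0, 1)])
        edges = adj.edges
        assert len(edges) == 5
        diagonals = [e for e in edges if e in ({0, 2}, {1, 3})]
        assert len(diagonals) == 1  # exactly one of the two diagonals

    def test_two_points_adjacent(self):
        adj = m.voronoi_adjacency([(0, 0), (5, 5)], ["x", "y"])
        assert adj.neighbors["x"] == {"y"}

    def test_duplicates_rejected(self):
        with pytest.raises(InputError):
            m.voronoi_adjacency([(0, 0), (0, 0), (1, 1)])

    def test_collinear_falls_back_to_chain(self):
        adj = m.voronoi_adjacency([(0, 0), (3, 0), (1, 0), (2, 0)], list("abcd"))
        # chain along the line: a-c-d-b
        assert adj.edges == {frozenset(p) for p in (("a", "c"), ("c", "d"), ("d", "b"))}


class TestTravelCost:
    def test_hand_example(self):
        times = {("s1", "f1"): 1.0, ("s2", "f2"): 2.0}
        cost = m.travel_cost({"s1": "f1", "s2": "f2"}, {"s1": 10, "s2": 20}, times)
        assert cost == pytest.approx(50.0)

    def test_colocated_sites_cost_zero(self):
        times = {("s1", "f1"): 0.0, ("s2", "f1"): 0.0}
        assert m.travel_cost({"s1": "f1", "s2": "f1"}, {"s1": 5, "s2": 7}, times) == 0.0

    def test_random_instance_matches_direct_sum(self):
        rng = np.random.default_rng(3)
        sites = [f"s{i}" for i in range(6)]
        facs = ["f1", "f2"]
        times = {(s, f): float(rng.uniform(0.1, 3)) for s in sites for f in facs}
        demands = {s: float(rng.uniform(10, 100)) for s in sites}
        assignment = {s: facs[i % 2] for i, s in enumerate(sites)}
        expected = sum(demands[s] * times[(s, assignment[s])] for s in sites)
        assert m.travel_cost(assignment, demands, times) == pytest.approx(expected)

    def test_missing_entry_rejected(self):
        with pytest.raises(InputError):
            m.travel_cost({"s1": "f9"}, {"s1": 1.0}, {("s1", "f1"): 1.0})


class TestShortageRatio:
    @pytest.mark.parametrize(
        "capacity, allocated, expected",
        [(100, 120, 0.2), (100, 80, 0.0), (100, 100, 0.0)],
    )
    def test_examples(self, capacity, allocated, expected):
        assert m.shortage_ratio(capacity, allocated) == pytest.approx(expected)

    def test_nonpositive_capacity_rejected(self):
        with pytest.raises(InputError):
            m.shortage_ratio(0.0, 10.0)


class TestSpatialCost:
    def _square_adj(self):
        return m.voronoi_adjacency([(0, 0), (1, 0), (1, 1), (0, 1)], list("abcd"))

    def test_per_site_term(self):
        adj = m.voronoi_adjacency([(0, 0), (1, 0), (0.4, 1)], list("abc"))
        total, terms = m.spatial_cost({"a": "F", "b": "F", "c": "F"}, adj, 1000.0)
        # each site has 2 same-assigned neighbors
        assert terms == {"a": -2000.0, "b": -2000.0, "c": -2000.0}
        assert total == -6000.0

    def test_gamma_zero(self):
        adj = self._square_adj()
        total, _ = m.spatial_cost({"a": "F", "b": "G", "c": "F", "d": "G"}, adj, 0.0)
        assert total == 0.0

    def test_single_facility_counts_every_edge_twice(self):
        adj = self._square_adj()
        total, _ = m.spatial_cost(dict.fromkeys("abcd", "F"), adj, 600.0)
        assert total == -600.0 * 2 * len(adj.edges)

    def test_total_is_even_multiple_of_gamma(self):
        adj = self._square_adj()
        total, _ = m.spatial_cost({"a": "F", "b": "F", "c": "G", "d": "G"}, adj, 7.0)
        assert (total / 7.0) % 2 == 0


class TestTotalCost:
    def test_arithmetic(self):
        b = m.total_cost(50.0, 0.2, -2000.0, (1000.0, 1.0))
        assert b.total == pytest.approx(-1750.0)
        assert (b.travel, b.capacity, b.spatial) == (50.0, 0.2, -2000.0)

    def test_conventional_reduction(self):
        assert m.total_cost(123.0, 9.0, -5.0, (0.0, 0.0)).total == 123.0

    def test_zero(self):
        assert m.total_cost(0, 0, 0, (1, 1)).total == 0.0


class TestMetropolis:
    def test_downhill_always_accepted(self):
        assert m.metropolis_accept(-5.0, 0.01, 0.999999)

    def test_large_uphill_rejected(self):
        assert not m.metropolis_accept(10.0, 1.0, 0.5)

    def test_zero_delta_accepted(self):
        assert m.metropolis_accept(0.0, 1.0, 0.999999)

    def test_uphill_accepted_when_draw_below_boltzmann(self):
        assert m.metropolis_accept(1.0, 2.0, math.exp(-0.5) - 1e-6)
        assert not m.metropolis_accept(1.0, 2.0, math.exp(-0.5) + 1e-6)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ScheduleError):
            m.metropolis_accept(1.0, 0.0, 0.5)


class TestProposeMove:
    def test_two_cross_assigned_sites_converge(self):
        adj = m.voronoi_adjacency([(0, 0), (1, 0)], ["a", "b"])
        rng = np.random.default_rng(0)
        new, changed = m.propose_move({"a": "F", "b": "G"}, adj, ["F", "G"], rng)
        assert changed
        assert new["a"] == new["b"]

    def test_single_facility_identity_flagged(self):
        adj = m.voronoi_adjacency([(0, 0), (1, 0)], ["a", "b"])
        rng = np.random.default_rng(0)
        new, changed = m.propose_move({"a": "F", "b": "F"}, adj, ["F"], rng)
        assert not changed
        assert new == {"a": "F", "b": "F"}

    def test_selection_frequencies_match_procedure(self):
        # fixed 8-site instance, fixed assignment: the procedure selects a
        # uniformly random eligible site, then a uniformly random
        # differently-assigned neighbor
        rng = np.random.default_rng(12)
        coords = rng.random((8, 2)) * 4
        sites = [f"s{i}" for i in range(8)]
        adj = m.voronoi_adjacency(coords, sites)
        assignment = {s: ("F" if i < 4 else "G") for i, s in enumerate(sites)}
        eligible = {
            i: [k for k in sorted(adj.neighbors[i])
                if assignment[k] != assignment[i]]
            for i in sites
        }
        eligible = {i: ks for i, ks in eligible.items() if ks}
        n_draw = 10_000
        counts = {}
        for _ in range(n_draw):
            new, _ = m.propose_move(assignment, adj, ["F", "G"], rng)
            (site,) = [s for s in sites if new[s] != assignment[s]]
            counts[site] = counts.get(site, 0) + 1
        for i, ks in eligible.items():
            p = 1 / len(eligible)
            sigma = math.sqrt(n_draw * p * (1 - p))
            assert abs(counts.get(i, 0) - n_draw * p) < 3.5 * sigma


def _toy_instance(rng, n_sites=6):
    sites = [f"s{i}" for i in range(n_sites)]
    coords = rng.random((n_sites, 2)) * 3
    adj = m.voronoi_adjacency(coords, sites)
    facs = ("A", "B")
    times = {(s, f): float(rng.uniform(0.1, 4)) for s in sites for f in facs}
    demands = {s: float(rng.uniform(100, 500)) for s in sites}
    caps = {"A": 900.0, "B": 700.0}
    cset = m.CandidateSet(facilities=facs, base_capacities=(caps["A"], caps["B"]))
    return sites, adj, facs, times, demands, caps, cset


class TestAnneal:
    def test_single_facility_is_direct(self):
        rng = np.random.default_rng(1)
        sites, adj, facs, times, demands, caps, _ = _toy_instance(rng)
        cset = m.CandidateSet(facilities=("A",), base_capacities=(2000.0,))
        times = {(s, "A"): times[(s, "A")] for s in sites}
        sol = m.anneal(cset, demands, times, adj, 100.0, (10.0, 1.0))
        assert set(sol.assignment.values()) == {"A"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_minimum_on_toy(self, seed):
        rng = np.random.default_rng(100 + seed)
        sites, adj, facs, times, demands, caps, cset = _toy_instance(rng)
        gamma, mult = 50.0, (800.0, 1.0)
        sol = m.anneal(cset, demands, times, adj, gamma, mult,
                       m.AnnealingSchedule(seed=seed))
        best_cost, best_assignment = oracle_exhaustive_minimum(
            sites, list(facs), demands, lambda i, j: times[(i, j)], caps,
            adj.edges, gamma, *mult,
        )
        assert sol.costs.total == pytest.approx(best_cost, rel=1e-9)

    def test_travel_only_objective_recovers_closest_assignment(self):
        rng = np.random.default_rng(42)
        sites, adj, facs, times, demands, caps, cset = _toy_instance(rng)
        # abundant capacity, gamma 0: only travel binds
        sol = m.anneal(cset, demands, times, adj, 0.0, (0.0, 1.0),
                       m.AnnealingSchedule(seed=3))
        closest = {s: min(facs, key=lambda f: times[(s, f)]) for s in sites}
        assert sol.assignment == closest

    def test_engines_bit_identical(self):
        from medloc import _engine

        if _engine.sa_step_jit is None:
            pytest.skip("numba unavailable")
        rng = np.random.default_rng(9)
        sites, adj, facs, times, demands, caps, cset = _toy_instance(rng)
        kwargs = dict(gamma=30.0, multipliers=(500.0, 1.0))
        a = m.anneal(cset, demands, times, adj, kwargs["gamma"],
                     kwargs["multipliers"], m.AnnealingSchedule(seed=5),
                     engine="python")
        b = m.anneal(cset, demands, times, adj, kwargs["gamma"],
                     kwargs["multipliers"], m.AnnealingSchedule(seed=5),
                     engine="numba")
        assert a.assignment == b.assignment
        assert np.array_equal(a.trace["best_cost"], b.trace["best_cost"])
        assert np.array_equal(a.trace["current_cost"], b.trace["current_cost"])

    def test_trace_best_nonincreasing_and_deterministic(self):
        rng = np.random.default_rng(8)
        sites, adj, facs, times, demands, caps, cset = _toy_instance(rng)
        sol1 = m.anneal(cset, demands, times, adj, 20.0, (300.0, 1.0),
                        m.AnnealingSchedule(seed=17), validate=True)
        sol2 = m.anneal(cset, demands, times, adj, 20.0, (300.0, 1.0),
                        m.AnnealingSchedule(seed=17))
        best = sol1.trace["best_cost"]
        assert np.all(np.diff(best) <= 1e-9)
        assert np.array_equal(best, sol2.trace["best_cost"])
        assert sol1.assignment == sol2.assignment

    def test_demand_is_conserved(self):
        rng = np.random.default_rng(2)
        sites, adj, facs, times, demands, caps, cset = _toy_instance(rng)
        sol = m.anneal(cset, demands, times, adj, 10.0, (100.0, 1.0),
                       m.AnnealingSchedule(seed=0))
        loads = {f: 0.0 for f in facs}
        for s, f in sol.assignment.items():
            loads[f] += demands[s]
        assert sum(loads.values()) == pytest.approx(sum(demands.values()))

    def test_every_site_assigned_within_set(self):
        rng = np.random.default_rng(21)
        sites, adj, facs, times, demands, caps, cset = _toy_instance(rng)
        sol = m.anneal(cset, demands, times, adj, 10.0, (100.0, 1.0),
                       m.AnnealingSchedule(seed=1))
        assert set(sol.assignment) == set(sites)
        assert set(sol.assignment.values()) <= set(facs)
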