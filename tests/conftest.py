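"""Shared fixtures and independent scoring oracles."""

from __future__ import annotations

import numpy as np
import pytest

import medloc as m


def oracle_total_cost(assignment, demands, time_of, capacities, edges,
                      gamma, lam_cap, lam_sp):
    """Independent first-principles objective, used to cross-check the package.

    ``time_of`` is a plain (site, facility) -> hours callable; ``edges`` an
    iterable of unordered neighbor pairs.
    """
    travel = sum(demands[i] * time_of(i, j) for i, j in assignment.items())
    loads: dict = {j: 0.0 for j in capacities}
    for i, j in assignment.items():
        loads[j] += demands[i]
    cap = sum(
        max(0.0, (loads[j] - capacities[j]) / capacities[j]) for j in capacities
    )
    mono = sum(1 for a, b in edges if assignment[a] == assignment[b])
    spatial = -gamma * 2.0 * mono
    return travel + lam_cap * cap + lam_sp * spatial


def oracle_exhaustive_minimum(site_ids, facility_ids, demands, time_of,
                              capacities, edges, gamma, lam_cap, lam_sp):
    """Brute-force minimum over all |facilities|^|sites| assignments."""
    import itertools

    best = (np.inf, None)
    for combo in itertools.product(facility_ids, repeat=len(site_ids)):
        assignment = dict(zip(site_ids, combo))
        c = oracle_total_cost(assignment, demands, time_of, capacities, edges,
                              gamma, lam_cap, lam_sp)
        if c < best[0]:
            best = (c, assignment)
    return best


@pytest.fixture(scope="session")
def micro_problem():
    instance = m.worked_micro_instance()
    return m.Problem.from_instance(instance)


@pytest.fixture(scope="session")
def micro_candidate_set(micro_problem):
    (cset,) = m.enumerate_candidate_sets(
        micro_problem.facility_ids, 2, micro_problem.capacities
    )
    return m.augment_capacities(
        cset, micro_problem.total_demand, 1.0, micro_problem.attractiveness
    )


@pytest.fixture(scope="session")
def tight_problem():
    instance = m.tight_capacity_instance()
    config = m.ModelConfig(
        gamma=instance.params["gamma"],
        increasing_factor=instance.params["increasing_factor"],
    )
    return m.Problem.from_instance(instance, config)


@pytest.fixture(scope="session")
def small_problem():
    """A 5-candidate instance small enough for full-table tests."""
    instance = m.generate_instance(
        n_cities=5, n_hospitals=7, n_waypoints=4, seed=11
    )
    return m.Problem.from_instance(instance)


@pytest.fixture(scope="session")
def small_table(small_problem):
    return m.evaluate_all(small_problem, 3, master_seed=5)
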