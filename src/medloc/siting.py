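"""Candidate-set enumeration and capacity augmentation.

The exact half of the model: every combination of P facilities from the n
candidates is enumerated (location-allocation problems of this kind are
small enough that exhaustive enumeration is both feasible and desirable,
since the downstream selection is visual-analytic over all alternatives).

When a set's total capacity falls short of total demand, a total increasing
capacity — the increasing factor times the deficit — is apportioned to the
set's facilities proportionally to their attractiveness scores. The
*capacity investment* of the set is the added capacity as a fraction of the
set's base capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb

from .errors import InputError

__all__ = ["CandidateSet", "enumerate_candidate_sets", "augment_capacities"]


@dataclass
class CandidateSet:
    """One combination of P candidate facilities with its capacities."""

    facilities: tuple
    base_capacities: tuple
    augmented_capacities: tuple = ()
    capacity_investment: float = 0.0

    def __post_init__(self) -> None:
        self.facilities = tuple(self.facilities)
        self.base_capacities = tuple(float(c) for c in self.base_capacities)
        if len(self.base_capacities) != len(self.facilities):
            raise InputError("one base capacity per facility required")
        if not self.augmented_capacities:
            self.augmented_capacities = self.base_capacities
        self.augmented_capacities = tuple(float(c) for c in self.augmented_capacities)
        if any(
            a < b - 1e-12
            for a, b in zip(self.augmented_capacities, self.base_capacities)
        ):
            raise InputError("augmented capacity may not fall below base capacity")

    @property
    def p(self) -> int:
        return len(self.facilities)

    @property
    def id(self) -> str:
        return "-".join(str(f) for f in self.facilities)

    def capacity(self, facility) -> float:
        return self.augmented_capacities[self.facilities.index(facility)]


def enumerate_candidate_sets(
    candidate_ids, p: int, capacities: dict | None = None
) -> list[CandidateSet]:
    """All C(n, p) combinations of candidates, in lexicographic order.

    ``capacities`` maps candidate id to base capacity; omitted candidates
    default to 0 capacity (augment before allocating in that case).
    """
    ids = sorted(candidate_ids, key=str)
    n = len(ids)
    if len(set(ids)) != n:
        raise InputError("candidate ids must be unique")
    if not 1 <= p <= n:
        raise InputError(f"p must satisfy 1 <= p <= {n}, got {p}")
    capacities = capacities or {}
    out = [
        CandidateSet(
            facilities=members,
            base_capacities=tuple(capacities.get(m, 0.0) for m in members),
        )
        for members in combinations(ids, p)
    ]
    assert len(out) == comb(n, p)
    return out


def augment_capacities(
    candidate_set: CandidateSet,
    total_demand: float,
    increasing_factor: float = 1.0,
    attractiveness: dict | None = None,
) -> CandidateSet:
    """Apply the capacity-augmentation rule to one candidate set.

    If the set already covers total demand it is returned unchanged with
    zero investment. Otherwise the total added capacity is
    ``increasing_factor * (total_demand - base capacity)``, shared among the
    facilities proportionally to their attractiveness scores; the capacity
    investment is the added capacity over the set's base capacity.
    """
    if increasing_factor < 0:
        raise InputError("increasing_factor must be non-negative")
    if total_demand < 0:
        raise InputError("total demand must be non-negative")
    base = candidate_set.base_capacities
    base_sum = sum(base)
    if base_sum >= total_demand or increasing_factor == 0.0:
        return replace(
            candidate_set,
            augmented_capacities=base,
            capacity_investment=0.0,
        )
    attractiveness = attractiveness or {}
    scores = [float(attractiveness.get(f, 0.0)) for f in candidate_set.facilities]
    if any(s < 0 for s in scores):
        raise InputError("attractiveness scores must be non-negative")
    score_sum = sum(scores)
    if score_sum <= 0:
        raise InputError(
            "cannot apportion added capacity: all attractiveness scores are zero"
        )
    total_add = increasing_factor * (total_demand - base_sum)
    additions = [total_add * s / score_sum for s in scores]
    if base_sum <= 0:
        raise InputError("set has zero base capacity; investment undefined")
    return replace(
        candidate_set,
        augmented_capacities=tuple(b + a for b, a in zip(base, additions)),
        capacity_investment=total_add / base_sum,
    )
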