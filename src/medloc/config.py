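"""Model configuration and field defaults.

Defaults mirror the Henan case study this model family was developed for:
a hospitalization rate alpha of 0.096, a complex-disease incidence theta of
0.1 (the fraction of hospitalized patients referred onward to a regional
healthcare center), an average length of stay of 10.4 days, and a speed
table for the five transportation categories (km/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

ROAD_CATEGORIES = ("secondary", "primary", "highway")
RAIL_CATEGORIES = ("railway", "high_speed_railway")
CATEGORIES = ROAD_CATEGORIES + RAIL_CATEGORIES

#: Speed limits in km/h per transportation category.
DEFAULT_SPEED_TABLE: dict[str, float] = {
    "secondary": 80.0,
    "primary": 100.0,
    "highway": 120.0,
    "railway": 120.0,
    "high_speed_railway": 300.0,
}

#: Attractiveness weights (key special departments, physicians/1000, beds/1000)
#: from an expert AHP elicitation; shipped as defaults so the AHP step is optional.
DEFAULT_WEIGHTS = (0.62, 0.252, 0.128)


@dataclass
class ModelConfig:
    """Bundle of tunable model parameters.

    Attributes
    ----------
    alpha : average rate of hospitalization (dimensionless, per resident).
    theta : incidence of complex diseases among hospitalized patients, i.e.
        the fraction referred to a regional healthcare center.
    alos : average length of stay, days.
    horizon_days : planning horizon used to convert beds into annual
        patient throughput.
    weights : attractiveness weights (w1, w2, w3) for key special
        departments, physicians per 1000 and beds per 1000.
    gamma : spatial-compactness weighting factor.
    increasing_factor : multiplier on the capacity deficit when a candidate
        set cannot cover total demand (1.0 covers the deficit exactly).
    lambda_capacity : multiplier making one unit of shortage ratio
        commensurable with travel cost; ``None`` means "derive from the
        instance" (median city travel cost, see solutions module).
    lambda_spatial : multiplier on the (negative) spatial cost.
    transfer_penalty_hours : travel time assigned to station link edges.
    snap_tolerance : coordinate tolerance (degrees) for merging segment
        endpoints into one network node.
    """

    alpha: float = 0.096
    theta: float = 0.1
    alos: float = 10.4
    horizon_days: float = 365.0
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    gamma: float = 600.0
    increasing_factor: float = 1.0
    lambda_capacity: float | None = None
    lambda_spatial: float = 1.0
    transfer_penalty_hours: float = 0.0
    snap_tolerance: float = 1e-6
    speed_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPEED_TABLE)
    )
    weighted_travel: bool = True
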