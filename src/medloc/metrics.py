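"""City demand, healthcare-center capacity and AHP-weighted attractiveness.

Three metrics drive the location-allocation model:

* **demand** of a city: potential patients with complex diseases that must be
  referred to a regional healthcare center, ``population * alpha * theta``;
* **capacity** of a center: residents it can serve per planning horizon,
  ``beds * horizon / AlOS`` (annual patient throughput for horizon 365 days);
* **attractiveness** of a center: a weighted sum of min-max normalized service
  quality variables (key special departments, physicians per 1000 residents,
  beds per 1000 residents), with weights elicited by the analytic hierarchy
  process (AHP) from a pairwise-comparison matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import InputError

__all__ = [
    "DemandSite",
    "CandidateFacility",
    "AhpJudgment",
    "AttractivenessWeights",
    "city_demand",
    "center_capacity",
    "ahp_weights",
    "minmax_normalize",
    "attractiveness",
    "aggregate_hospitals",
]

#: Saaty's random consistency index, indexed by matrix order.
RANDOM_CONSISTENCY_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}


@dataclass
class DemandSite:
    """A demanding city with its population-derived referral demand."""

    id: str
    name: str
    lon: float
    lat: float
    population: float
    demand: float | None = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise InputError(f"negative population for demand site {self.id!r}")


@dataclass
class CandidateFacility:
    """A candidate healthcare center, aggregated over a city's hospitals.

    ``ksd``, ``ptr`` and ``btr`` are the service-quality variables: number of
    key special departments, physicians per thousand residents and beds per
    thousand residents.
    """

    id: str
    city_id: str
    lon: float
    lat: float
    beds: float
    ksd: float
    ptr: float
    btr: float
    capacity: float | None = None
    attractiveness: float | None = None


@dataclass
class AhpJudgment:
    """A positive reciprocal pairwise-comparison matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InputError("judgment matrix must be square")
        if not np.all(a > 0):
            raise InputError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise InputError("judgment matrix diagonal must be 1")
        if not np.allclose(a * a.T, 1.0, rtol=1e-7, atol=1e-9):
            raise InputError("judgment matrix is not reciprocal (a_ij != 1/a_ji)")
        self.matrix = a


@dataclass
class AttractivenessWeights:
    """Normalized priority weights plus the AHP consistency ratio."""

    w1: float
    w2: float
    w3: float
    consistency_ratio: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


def city_demand(population: float, alpha: float = 0.096, theta: float = 0.1) -> float:
    """Referral demand of a city: ``population * alpha * theta``.

    ``alpha`` is the average hospitalization rate and ``theta`` the incidence
    of complex diseases requiring referral, both in [0, 1].
    """
    if population < 0:
        raise InputError("population must be non-negative")
    if not (0 <= alpha <= 1) or not (0 <= theta <= 1):
        raise InputError("alpha and theta must lie in [0, 1]")
    return population * alpha * theta


def center_capacity(beds: float, alos: float = 10.4, horizon: float = 365.0) -> float:
    """Patients a center can serve over ``horizon`` days: ``beds * horizon / alos``."""
    if beds < 0:
        raise InputError("beds must be non-negative")
    if alos <= 0:
        raise InputError("average length of stay must be positive")
    if horizon <= 0:
        raise InputError("horizon must be positive")
    return beds * horizon / alos


def ahp_weights(judgment: AhpJudgment | np.ndarray) -> AttractivenessWeights:
    """Priority weights from a reciprocal judgment matrix.

    Returns the principal eigenvector normalized to sum one, together with
    the consistency ratio CR = ((lambda_max - n)/(n - 1)) / RI(n), where RI
    is Saaty's random consistency index. A warning is emitted when CR exceeds
    0.1, the conventional acceptability bound. The matrix order must be 3:
    one weight per service-quality variable.
    """
    if not isinstance(judgment, AhpJudgment):
        judgment = AhpJudgment(np.asarray(judgment, dtype=float))
    a = judgment.matrix
    n = a.shape[0]
    if n != 3:
        raise InputError("expected a 3x3 judgment matrix (three variables)")
    eigvals, eigvecs = scipy.linalg.eig(a)
    k = int(np.argmax(eigvals.real))
    lam_max = float(eigvals[k].real)
    v = np.abs(eigvecs[:, k].real)
    w = v / v.sum()
    ri = RANDOM_CONSISTENCY_INDEX[n]
    cr = max(((lam_max - n) / (n - 1)) / ri, 0.0)
    if cr > 0.1:
        warnings.warn(
            f"AHP consistency ratio {cr:.3f} exceeds 0.1; "
            "expert judgments may be incoherent",
            UserWarning,
            stacklevel=2,
        )
    return AttractivenessWeights(*map(float, w), consistency_ratio=cr)


def minmax_normalize(values) -> np.ndarray:
    """Min-max normalization onto [0, 1].

    Degenerate ranges (all values equal, including a singleton) map to 1.0:
    every facility then attains the full score on that variable.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InputError("cannot normalize an empty list")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones_like(v)
    return (v - lo) / (hi - lo)


def attractiveness(
    facilities: list[CandidateFacility],
    weights: AttractivenessWeights | tuple[float, float, float] = (0.62, 0.252, 0.128),
) -> dict[str, float]:
    """Attractiveness score per facility, in [0, 1].

    ``score = w1*Norm(ksd) + w2*Norm(ptr) + w3*Norm(btr)`` with min-max
    normalization computed across the candidate set. Scores are also written
    back onto the facility objects.
    """
    if not facilities:
        raise InputError("attractiveness requires at least one facility")
    if isinstance(weights, AttractivenessWeights):
        weights = weights.as_tuple()
    for f in facilities:
        for attr in ("ksd", "ptr", "btr"):
            if getattr(f, attr) is None:
                raise InputError(f"facility {f.id!r} is missing attribute {attr!r}")
    w1, w2, w3 = weights
    ksd = minmax_normalize([f.ksd for f in facilities])
    ptr = minmax_normalize([f.ptr for f in facilities])
    btr = minmax_normalize([f.btr for f in facilities])
    scores = w1 * ksd + w2 * ptr + w3 * btr
    out: dict[str, float] = {}
    for f, s in zip(facilities, scores):
        f.attractiveness = float(s)
        out[f.id] = float(s)
    return out


def aggregate_hospitals(hospitals: pd.DataFrame, cities: list[DemandSite]) -> list[CandidateFacility]:
    """Aggregate individual hospitals into one candidate facility per city.

    ``hospitals`` needs columns ``city_id, beds, ksd, ptr, btr``; attribute
    information of a candidate is the summation of its hospitals' data, and
    its location is the city's location. Cities without hospitals yield no
    candidate.
    """
    required = {"city_id", "beds", "ksd", "ptr", "btr"}
    missing = required - set(hospitals.columns)
    if missing:
        raise InputError(f"hospital table is missing columns: {sorted(missing)}")
    city_by_id = {c.id: c for c in cities}
    out = []
    grouped = hospitals.groupby("city_id", sort=True)[["beds", "ksd", "ptr", "btr"]].sum()
    for city_id, row in grouped.iterrows():
        if city_id not in city_by_id:
            raise InputError(f"hospital table references unknown city {city_id!r}")
        c = city_by_id[city_id]
        out.append(
            CandidateFacility(
                id=str(city_id), city_id=str(city_id), lon=c.lon, lat=c.lat,
                beds=float(row["beds"]), ksd=float(row["ksd"]),
                ptr=float(row["ptr"]), btr=float(row["btr"]),
            )
        )
    return out
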