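# Methods

This note records the model implemented by `medloc`, its assumptions, the
parameter defaults and the numerical and design choices made where the
design was genuinely open.

## Model

### Siting: exhaustive enumeration with capacity augmentation

Candidate facilities are cities (attributes aggregated over their
hospitals). All C(n, P) subsets are enumerated in lexicographic order —
regional siting problems are small enough that exhaustiveness is preferable
to pruning, because the downstream selection is visual-analytic over *all*
alternatives, not just the argmin.

For a set whose base capacity Σ cap_j falls short of total demand D, a
total added capacity `f · (D − Σ cap_j)` (increasing factor f, default 1.0:
cover the deficit exactly) is apportioned to members proportionally to
their attractiveness scores, which are frozen before augmentation
(augmentation does not feed back into the beds-per-1000 variable). The
**capacity investment** reported per set is the added capacity divided by
the set's base capacity. With f = 0 no augmentation happens and the deficit
persists into the capacity cost — the setting the tight-capacity fixture
uses (see below).

### Allocation: simulated annealing

For one candidate set, an allocation `a` maps every demand site to exactly
one member facility (the P-median feasibility constraints hold for every
intermediate state by construction of the move). The objective is

    total = travel + λ_cap · capacity + λ_sp · spatial

* travel = Σ_i w_i · t(i, a(i)), demand-weighted travel time (a switch
  allows unweighted time; weighted is the default since demand weighting is
  what makes the P-median objective a population measure);
* capacity = Σ_j max(0, (load_j − cap_j)/cap_j), the shortage ratio summed
  over the set. It is clamped at zero for surplus facilities: spare
  capacity does not reward the objective, it is merely not penalized;
* spatial = Σ_i −γ · |{k ∈ N(i) : a(k) = a(i)}| with N the Voronoi/Delaunay
  neighbor relation of the demand sites. Each adjacency is counted from
  both endpoints (the definition is per demand point), so the total is
  −γ·2·(monochromatic Delaunay edges) and always an even multiple of γ.

The annealer starts from a uniformly random feasible assignment. A move
picks a uniformly random site among those with at least one
differently-assigned Voronoi neighbor — equivalent to resampling a uniform
site until one qualifies — then a uniformly random such neighbor, and the
site *adopts* the neighbor's facility. Propagation (rather than a pairwise
swap) was chosen because it changes facility load totals, which the
capacity term must be able to explore; when every site already shares one
facility, the picked site jumps to a uniformly random other member. Moves
are accepted by the Metropolis criterion (accept if Δ ≤ 0, else with
probability exp(−Δ/t)); Δ = 0 is accepted with probability one. The
best-so-far assignment, not the final state, is returned, since Metropolis
can end uphill.

Cost updates inside the loop are incremental (O(degree) per move); the
running cost is re-synchronized from scratch at every temperature step so
floating-point drift cannot accumulate, and the returned solution is always
re-scored from its assignment, which makes exported rows reproduce their
five values exactly on re-scoring.

### Cooling schedule

None of the schedule constants are canonical, so the defaults are standard
simulated-annealing practice, all overridable:

| parameter | default | rationale |
| --- | --- | --- |
| t0 | 2 × std of ΔE over 100 random-walk moves | adapts the temperature to the cost scale of the instance |
| cooling factor | 0.95 | geometric cooling, ~135 temperature steps |
| iterations per temperature L | 100 × number of sites | neighborhood size scales with n |
| t_min | 1e-3 × t0 | three decades of cooling |

The inner loop is written once as plain array code and compiled with numba;
the uncompiled path is the same source consuming the same pre-drawn
uniforms, so both engines are bit-identical and the pure-Python path can be
used for step-by-step validation. All randomness flows from one seed
(initial assignment → t0 probe → move/acceptance uniforms, in that order),
so runs are bit-reproducible. In `evaluate_all`, per-set seeds are derived
from the master seed and the set index via `numpy.random.SeedSequence`, so
each set is independently reproducible and parallelizable.

### Objective multipliers

The three cost terms have incommensurable units (person-hours, ratios,
γ-units). λ_sp defaults to 1 — γ itself carries the spatial scale, and the
γ sweep (200…2000, with 600 as the shipped default) is the intended tuning
instrument. λ_cap defaults to the *median city's travel cost*: the median
over sites of demand_i × (median travel time to the candidate facilities),
so one unit of shortage ratio costs about as much as relocating a typical
city's demand. The median (not minimum) time is used because candidates are
co-located with cities, making every nearest time zero. Both multipliers
are configurable; setting γ = 0 and λ_cap = 0 reduces the model exactly to
the conventional P-median, which the test suite exploits as an oracle.

## Transportation network

Raw polyline segments carry one of five categories with speed limits
80/100/120/120/300 km/h; edge travel time is length divided by speed.
Segment lengths come from an explicit `length_km` field when present
(surveyed lengths), else from the great-circle polyline length.

Topology building merges segment endpoints within a snap tolerance
(default 1e-6 degrees) into shared nodes — separately for the road and rail
subnetworks: a rail endpoint is never merged with a road node, because the
railway is physically accessible only through stations. Each station adds
one node and exactly two link edges, to the nearest road segment and the
nearest railway segment, splitting each at the projection point. Link
edges default to zero travel time, with a configurable per-transfer penalty
(the data give no boarding/waiting time; the penalty enables sensitivity
checks). Node ids are consecutive integers from 1, assigned by sorting
cluster coordinates, so identical input yields identical numbering.

Demand sites and facilities are snapped to the nearest network node by
Euclidean distance (ties to the smallest id); there is no off-network
access time. Shortest times use Dijkstra per origin; an unreachable pair
raises an error listing the connected components rather than returning
infinity, since a correctly built study network is connected.

The Voronoi neighbor relation is computed as Delaunay connectivity on an
equirectangular projection about the instance centroid — at provincial
scale the projection distortion is negligible for adjacency. Collinear
site sets (degenerate triangulations) fall back to chain adjacency along
the line; two sites are always neighbors.

## Metrics

* City demand = population × α × θ with α = 0.096 (average hospitalization
  rate) and θ = 0.1 (incidence of complex diseases among the hospitalized,
  i.e. the referred fraction).
* Center capacity = beds × horizon / AlOS with AlOS = 10.4 days and horizon
  365 days — annual patient throughput, the only dimensionally consistent
  reading of "residents a center can serve".
* Attractiveness = w1·Norm(ksd) + w2·Norm(ptr) + w3·Norm(btr), min-max
  normalized across the candidate set; a degenerate range maps to 1.0 so a
  variable that does not discriminate does not penalize anyone. Default
  weights (0.62, 0.252, 0.128) ship as configuration; `ahp_weights` can
  recompute them from a 3×3 reciprocal judgment matrix via the principal
  eigenvector, with the consistency ratio CR = ((λmax − n)/(n − 1))/RI(n)
  (Saaty's RI, RI(3) = 0.58) and a warning above the conventional 0.1.

## Synthetic instances

The generator emulates the structure of a province-scale study area:
17 cities, 38 hospitals, and a mixed network whose length shares target
42.1/13.0/31.1/10.5/2.3 percent across the five categories (the printed
percentages sum to 99 after rounding and are renormalized). Cities are
blue-noise sampled in the bounding box with log-uniform populations;
roads are a Gabriel graph (connected, planar, contains the Euclidean MST)
over cities plus waypoints, with gentle midpoint curvature and categories
assigned greedily to match the road-share targets by length; one railway
and one high-speed corridor are threaded through the most populous cities
(high-speed rail aggregates demand along the corridor, a behavior the
fixture must be able to reproduce), joined to roads only via stations; and
hospitals are allocated to cities with a population-skewed multinomial.
Road-category shares are matched exactly by construction up to edge
granularity; rail shares follow from corridor geometry and land within
±10 percentage points of the targets at the default size.

What the generator does **not** emulate: real road geometry and density
(~29 000 segments at province scale vs ~10^2–10^3 here), terrain, travel
behavior and congestion, or the spatial autocorrelation of hospital
quality. Passing tests therefore demonstrate correctness of the model and
algorithms under structurally realistic inputs, not calibrated predictions
for any real province.

Two fixed fixtures are hand-written:

* the **micro fixture** (8 cities, one candidate pair) is small enough to
  enumerate all 256 allocations; its exhaustive optimum is frozen in
  `medloc/data/micro_optimum.json` (produced by the package's own
  enumeration, cross-checked in the tests by an independent brute force)
  and the annealer is required to attain it;
* the **tight-capacity fixture** (16 cities, 4 candidates) was constructed
  so that the travel-optimal pair of candidates is capacity-poor and its
  closest-assignment split slices through a dense demand cluster, while a
  capacious pair splits the plane along a sparse gap. It runs with
  increasing factor 0 — augmentation disabled — because with the deficit
  covered, capacity pressure vanishes and both models coincide; with it
  binding, the modified model trades a few percent of travel cost for
  strictly lower capacity and spatial costs, the qualitative pattern the
  comparison is meant to expose.

## Problem sizes and numerical choices

The shipped study-scale configuration (17 cities → 680 candidate sets,
~1000-edge network) evaluates in well under a minute with the compiled
engine; the acceptance script's full run, including 50 reduction instances
and 200 random network checks, takes a few minutes on one CPU.

Ties: closest-facility assignment breaks ties toward the lexicographically
smaller facility id; node snapping toward the smaller node id; solution
ranking sorts ascending (most negative spatial cost first) with
lexicographic member-id tie-break. Shortage ratios require positive
capacity; zero-capacity members must be augmented before allocation.
Judgment matrices are validated as positive reciprocal with unit diagonal —
a matrix scaled by k ≠ 1 is rejected rather than silently renormalized.

## Known limitations

* Turn restrictions, one-way streets, congestion, timetables and mode
  choice are out of scope; travel time is free-flow length/speed.
* The annealer is a heuristic: optimality is only guaranteed against the
  enumerable fixtures; at study scale the restart mechanism
  (`n_restarts`) mitigates but does not eliminate the variance inherent
  to simulated annealing.
* Facility attributes enter only through capacity and attractiveness;
  hospitalization-rate heterogeneity across cities is not modeled.
* The package computes and exports the solution table; the interactive
  visual analytics happen in external tools.
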