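# Methods

## Model

A district instance is a capacitated vehicle routing problem with one
depot, per-center demand in two storage classes (cold / dry), a
heterogeneous fleet, asymmetric distances, categorical road conditions and
a hard route-duration limit. The duration limit plays two roles: driver
working time and the holding time of passive cold boxes.

**Preprocessing.** Per-product demand is scaled to available supply
(proportionally per product, rounded to whole units by largest remainder,
ties by center order — the delivered total never exceeds supply), then
aggregated into per-center cold and dry volumes `D_i^r = Σ_p d_ip k_p`
(cold products) and `D_i^d` (dry). The optimization always sees exactly
two product classes regardless of the product count; per-product detail is
restored post hoc by the report module, which fills products back into
route deliveries class by class and verifies exact volume reconciliation.

**Objective.** Arc `(i, j, v)` costs
`W_t e^(−h/μ_h) + W_p (e^(−γ/μ_γ) + e^(−β/μ_β))`, with `h = distance /
vehicle velocity`. The exponentials-of-scaled-values normalize the three
ingredients to comparable magnitude. Note the printed form is *decreasing*
in time and penalty, which runs against the intuition that longer/riskier
arcs should cost more; because every arc cost is strictly positive, the
minimization still produces sensible compact routes (extra arcs always add
cost), and this form's objective magnitudes match the published per-district
values, so it is the default. An `increasing` form (positive exponents) is
provided as a first-class alternative; every solver and test path supports
both. The discrepancy is documented rather than resolved.

**Scaling means.** `μ_h = Σ_v Σ_{i,j} 2 h_ijv / (|V||C|²)` — the factor 2
is kept as a deliberate convention (a config flag can disable it); `μ_γ`
averages all `|C|²` road-penalty entries including the zero diagonal and
unavailable arcs (whose penalty is stored as 0); `μ_β`, `μ_cr`, `μ_cd`,
`μ_v` are plain fleet means. Zero means (e.g. a fleet with no cold
capacity at all) degrade gracefully: the affected exponent ratio is taken
as 0.

**Penalty scales.** Road conditions (7 ordered labels, fully paved … not
accessible) and vehicle reliability (4 labels) are entered as categories;
the numeric penalties are code-level configuration, not user data:
road 1/2/3/5/6/8 for the six passable labels, vehicle 1/2/3/4. "Not
accessible" has no penalty — the arc is excluded from routing entirely.
Blank distance cells are schema errors; unavailability must be expressed
through the road condition, never by missing data.

## Exact MIP

Variables: binary `y_ijv` (arc use, including the fixed-to-zero diagonal),
continuous `x_ijvp` (class volume on an arc, liters) and `t_iv` (departure
time), giving `3|C|²|V| + |C||V|` variables — 200/400/600/374/1568/3120
for the six published district shapes. Constraint families: flow
conservation `Σ_i Σ_v (x_ijvp − x_jivp) = D_jp` applied at every center
except the depot (the depot is the source; applying it there would demand
supply consumption at the depot itself); initial-load capacity per class;
big-M time propagation `t_j ≥ t_i + h + W − M(1 − y_ijv)` for `j ≠ o`
(doubles as subtour elimination); depot-return guarantee
`t_i + W(1 − y_iov) + y_ijv (h_ij + h_jo) ≤ l` for all `i, j, v`;
depot-departure linking for `y` (arc count ≤ |C|² × departures) and for
`x`; degree balance; availability and no-self-arc as variable bounds; and
flow-arc linking `x ≤ M y`.

Big-M values: `M_time = l + W + max h`; `M_count = |C|²`;
`M_flow,p = max(Σ_i D_ip, |C|)` — the floor at `|C|` keeps the
depot-departure flow linking a pure on/off switch even when total demand
volume is small (an arc's flow never exceeds total demand, and a route of
at most `|C|` arcs carries at most `|C|` times its initial load). The test
suite checks that inflating every M tenfold leaves optima unchanged.

The backend is HiGHS branch-and-cut through `scipy.optimize.milp` with
sparse constraint matrices; relative gap 1e−6 for optimality claims. The
model permits split deliveries and pass-through visits as written; route
extraction walks the arc set from the depot in departure-time order and
treats any leftover arcs (a cycle avoiding the depot) as an integrity
error, since time propagation makes them impossible.

## Index construction and search

The greedy construction and its branch-and-bound wrapper are described in
the README. Details that matter:

* **Feasibility check.** An extension to center `j` requires the road from
  the current endpoint *and the return road `j → depot`* to be available,
  remaining cold/dry capacity, and
  `t + h(last, j) + W + h(j, o) ≤ l`. The return-road availability check
  is included because without it a route could strand at a center it can
  enter but not leave toward the depot.
* **Vehicle cycling.** Vehicles are ordered by decreasing vehicle index
  (ties by input order) and cycled; a vehicle is reused only after every
  vehicle has had a turn. A turn may be empty (the vehicle can serve no
  remaining center); a full cycle of empty turns with demand outstanding
  is an infeasibility, reported with the unservable centers' names.
* **Initial branches.** One branch per feasible first center of the
  top-indexed vehicle, plus (when the fleet has more than one vehicle) one
  branch in which that vehicle takes an empty turn. The extra branch is
  needed for exhaustive optimality: the optimum may not use the
  top-indexed vehicle at all, and no first-center branch can represent
  that.
* **Elite set.** With `n` initial branches the elite has
  `max(1, ⌈0.12 n⌉)` slots, half filled by best incumbent value (greedy
  depth evaluation of each branch), half by largest uncertainty
  (incumbent − branch lower bound), remainder-first; ties by branch label.
  With at least two branches each half gets at least one slot. Elite
  branches are explored first; remaining branches follow, so an uncapped
  run is exhaustive and exact (the elite only prioritizes).
* **Bounds.** Lower bound of a node = committed arc cost + MST weight over
  {unserved centers} ∪ {current endpoint, depot}, on the undirected graph
  whose pair cost is the minimum arc cost over directions and vehicles.
  Any feasible completion's arcs span that node set and each costs at
  least the pair cost, so the MST weight is a valid bound under either
  objective form. If availability disconnects the set, the bound covers
  the depot's component and a warning is attached. The global bound is
  the minimum over still-open nodes, floored by the root MST bound and
  capped at the incumbent.
* **Exploration order.** Depth-first within a branch, children by
  decreasing node index (the route-closing/turn-skipping child last), ties
  by center order; branches served round-robin with a quantum of 1000 node
  expansions under the shared time budget. No randomness anywhere; two
  runs are bit-identical.
* **Greedy ranking vs pruning.** The construction ranks extensions by the
  node index in both objective forms (the index is the architecture);
  pruning and incumbent comparison always use the actual objective.

**Equivalence of the three routes to the optimum.** The MIP admits plans
the construction search cannot represent (split deliveries; passing
through a center without delivering), and the exponential arc costs do not
satisfy the triangle inequality, so MIP-optimum = search-optimum is not a
theorem. Under the study conditions used throughout the tests (compact
districts, all penalties from the default scales, fleet capacity sized to
demand) the per-arc penalty floor makes extra visits uneconomical: across
hundreds of instances and both objective forms the MIP optimum, the
uncapped search optimum and a single-visit brute-force enumerator agreed
to 1e−6, and the test suite asserts exactly that on its 50-instance suite.

## Synthetic districts

The generator emulates district structure: centers uniform in a square
(default 80 km side; 150 km for 50-center stress shapes), asymmetric
distances = Euclidean × (1 + jitter) drawn per direction (one-way roads,
detours), road conditions drawn per unordered pair from a label
distribution (depot roads never "not accessible", keeping instances
connected), integer monthly demand with ~20% structural zeros, and fleet
capacity set to `capacity_tightness ×` total demand volume (each vehicle
floored at 1.05 × the largest single center, so no center is inherently
unservable). Tightness well above 1 yields one route per vehicle;
near/below 1 provably forces multi-route plans (fleet capacity < total
volume), exercising the reuse rule. Supply defaults to 1.3 × demand, so
demand scaling is off unless a test lowers it deliberately.

What the generator does **not** emulate: real road-network topology
(distances are jittered Euclidean, not shortest paths), seasonal
availability, demand uncertainty, correlated product volumes. Passing
tests therefore certify algorithmic correctness on district-*shaped*
inputs, not calibration to any real district.

The exhaustive-check family (`oracle_suite_spec`) uses 4–6 centers, 1–2
vehicles, 4 products, a 50 km field, a 10 h limit, ample capacity and no
inaccessible roads, so that every instance is feasible and small enough to
enumerate completely.

The four-center walkthrough fixture (depot + a, b, c, one vehicle with
penalty 1, velocity 60 km/h) uses hand-chosen synthetic distances and road
conditions designed so all node-index values along the construction are
distinct; it pins down the index mechanics in tests.

## Numerical choices and limitations

* Feasibility tolerances: 1e−9 (hours/liters) in construction, 1e−6 in
  the independent audit; MIP relative gap 1e−6.
* All tie-breaks are lexicographic (center index, vehicle input order);
  there is no randomness outside the seeded generator.
* Costs (fuel = km × L/km × price; one per-diem per route, since a route
  fits in one working day) are computed after optimization and never
  influence it.
* Clock times are formatted HH:MM modulo 24 h from the configured start
  time; multi-day routes are out of scope, as are transfers between
  centers, time windows, and map-API distance acquisition.
* The published constraint counts for the district shapes cannot be
  reconciled with any counting of the printed constraint families; the
  model reports its own constraint count but asserts nothing about it.
  Likewise the published 50-center variable counts are consistent with 40
  centers under the counting that fits the other six shapes, so the
  50-center rows are excluded from the variable-count reproduction.
* Problem sizes in the default test run (≤ 6 centers for exhaustive
  checks, 11–16 for property checks, one 50-center construction) were
  chosen to keep the whole suite under a minute while still covering the
  multi-route, split-delivery and scale regimes.
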