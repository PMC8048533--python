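# coldroute

Route planning for last-mile distribution of vaccines and medical supplies
in districts with unreliable roads, heterogeneous vehicles and limited cold
storage. The package is written for health-logistics planners and
operations researchers: it turns a district description (health centers,
fleet, products, demand, road conditions) into executable delivery routes
with schedules, delivered quantities and costs — quickly enough to be used
interactively.

## The problem and the model

One district store (the depot, `o`) supplies a set of health centers `C`
with products `P` that are either refrigerated ("cold", carried in a
vehicle's cold box) or dry. Each vehicle `v` has separate cold and dry
volume capacities `c_vr`, `c_vd`, an average velocity, and a reliability
class mapped to a penalty `β_v`; each road `(i, j)` has an asymmetric
distance, a condition label mapped to a penalty `γ_ij`, and an availability
flag `a_ij` (impassable roads are simply excluded). Every route starts and
ends at the depot, spends a drop-off time `W` at each visited center, and
must finish within the route limit `l` (typically one 8-hour working day,
which also protects the cold chain).

Products are grouped into the two storage classes during preprocessing, so
the optimization sees per-center cold/dry demand volumes `D_i^r`, `D_i^d`;
per-product quantities are restored afterwards for reporting. Demand above
the available supply is scaled back proportionally (whole units, largest
remainder).

The objective is a weighted sum over used arcs `(i, j, v)`:

    W_t · e^(−h_ijv/μ_h)  +  W_p · ( e^(−γ_ij/μ_γ) + e^(−β_v/μ_β) )

where `h_ijv` is the transit time, the `μ` are instance-wide means that put
the terms on one scale, and the user chooses the transit-time weight
(`W_t + W_p = 1`). An alternative "increasing" form with positive
exponents is available (see `docs/methods.md` for why both exist).

Two solvers share this model:

* **`mip`** — the exact mixed-integer program (binary arc variables,
  continuous flows and departure times, big-M time propagation), solved
  with HiGHS branch-and-cut via SciPy.
* **`greedy` / `bnb`** — a two-stage index rule: vehicles are ranked by
  `e^(−β_v/μ_β) + e^(c_vr/μ_cr) + e^(c_vd/μ_cd) + e^(v_v/μ_v)`, and the
  active route repeatedly adds the feasible unserved center maximizing
  `W_t e^(−h_ijv/μ_h) + W_p e^(−γ_ij/μ_γ)`. All vehicles get a turn
  before any is reused. `bnb` embeds this construction in an elite-set
  branch-and-bound (12% of the initial branches, half best incumbents,
  half largest uncertainty intervals) with minimum-spanning-tree lower
  bounds — anytime, never worse than the plain construction, and exact
  when given enough time.

## Worked example

```
$ coldroute generate --centers 8 --vehicles 2 --seed 7 --output district
wrote district
$ coldroute solve district --solver bnb --budget 30 --output district_plan
objective: 4.5127
bound:     4.5127
gap:       0.0000
routes:    1
output:    district_plan
```

The objective 4.5127 is the arc-cost sum of the best plan found; bound is
the proven lower bound, so gap 0.0000 certifies optimality here. One route
suffices: the top-indexed vehicle (`V1`) can carry the whole district's
demand. The result directory holds two tables. `routes.csv` starts with a
per-route summary, then per-leg detail:

```
record,route,vehicle,vehicle_condition,from_center,to_center,road_condition,departure,distance_km,duration_hours,fuel_cost,per_diem_cost,...
summary,0,V1,somewhat reliable,Depot,Depot,,08:00,322.0,7.321,60.38,36.79,...
leg,0,V1,somewhat reliable,Depot,C07,dirt road (good quality),08:00,43.1,0.746,...
leg,0,V1,somewhat reliable,C07,C04,dirt road (good quality),09:00,25.7,0.445,...
```

i.e. a 322 km, 7.3 h tour departing 08:00, costing 60.38 in fuel and one
36.79 per-diem; `products.csv` lists the doses/units of each product to
unload at each center. Instances can equally be real district workbooks
(`.xlsx` with the seven input sheets: parameters, products,
center_capacities, demand, vehicle, distance_data, road_condition).

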