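"""Exact mixed-integer programming formulation of the routing problem.

Decision variables on the grouped (cold/dry) instance with center set C,
vehicle set V and the two product classes:

* ``y[i,j,v]``  binary — vehicle v drives arc (i, j);
* ``x[i,j,v,p]`` continuous, liters — volume of class p carried on (i, j, v);
* ``t[i,v]``   continuous, hours — time vehicle v departs center i.

Constraint families: flow conservation delivering each center's demand
(applied at every center except the depot, which is the source); initial
cold/dry loads within vehicle capacities; big-M time propagation along used
arcs (which doubles as subtour elimination, since time strictly increases
along any arc chain away from the depot); guaranteed return to the depot
within the route time limit; depot-departure linking for both y and x;
degree balance (a vehicle entering a center leaves it); no self-arcs; arc
availability; and flow-arc linking.

The solver backend is HiGHS branch-and-cut via ``scipy.optimize.milp``;
matrices are assembled sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .objective import Route, Solution, arc_cost, arc_cost_matrix  # noqa: F401 (arc_cost re-exported)
from .preprocess import GroupedInstance


class BuildError(ValueError):
    """Degenerate instance: the model cannot be built."""


class SolutionIntegrityError(RuntimeError):
    """Solver returned arcs that do not decompose into depot-rooted routes."""


def count_variables(n_centers: int, n_vehicles: int) -> int:
    """Decision-variable count of the grouped model: binary y over C x C x V,
    continuous x over C x C x V x {cold, dry}, continuous t over C x V."""
    return 3 * n_centers * n_centers * n_vehicles + n_centers * n_vehicles


@dataclass
class MIPConfig:
    """Big-M values and solver knobs.

    ``m_time`` relaxes the time-propagation constraints; it only needs to
    exceed any feasible time difference, l + W + max h.  ``m_count`` bounds
    the number of arcs one vehicle can use (|C|^2).  ``m_flow`` per class
    bounds any single arc flow (total demand volume, floored at |C| so the
    depot-departure linking over all arcs stays a pure on/off switch).
    """

    m_time: float = 0.0
    m_count: float = 0.0
    m_flow: tuple[float, float] = (0.0, 0.0)
    time_limit: float = 300.0
    mip_rel_gap: float = 1e-6
    objective_form: str | None = None  # None -> grouped.config.objective_form
    backend: str = "highs"

    @staticmethod
    def for_instance(grouped: GroupedInstance, **overrides) -> "MIPConfig":
        inst = grouped.instance
        l = inst.parameters.max_route_hours
        w = inst.parameters.dropoff_time
        n = grouped.n_centers
        cfg = MIPConfig(
            m_time=l + w + float(grouped.transit.max(initial=0.0)),
            m_count=float(n * n),
            m_flow=(
                max(float(grouped.cold_volume.sum()), float(n)),
                max(float(grouped.dry_volume.sum()), float(n)),
            ),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class MIP:
    """Assembled model ready for the backend."""

    grouped: GroupedInstance
    config: MIPConfig
    c: np.ndarray  # objective coefficients
    A: sparse.csc_matrix
    lb: np.ndarray  # constraint lower bounds
    ub: np.ndarray  # constraint upper bounds
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray

    @property
    def n_variables(self) -> int:
        return self.c.size

    @property
    def n_constraints(self) -> int:
        return self.A.shape[0]

    # --- variable indexing -------------------------------------------------
    def iy(self, i: int, j: int, v: int) -> int:
        n = self.grouped.n_centers
        return v * n * n + i * n + j

    def ix(self, i: int, j: int, v: int, p: int) -> int:
        n, nv = self.grouped.n_centers, self.grouped.n_vehicles
        return n * n * nv + p * n * n * nv + v * n * n + i * n + j

    def it(self, i: int, v: int) -> int:
        n, nv = self.grouped.n_centers, self.grouped.n_vehicles
        return 3 * n * n * nv + v * n + i


@dataclass
class MIPSolution:
    y: np.ndarray  # (n, n, nv) binary
    x: np.ndarray  # (n, n, nv, 2) liters
    t: np.ndarray  # (n, nv) hours
    objective: float
    bound: float
    gap: float
    status: str  # optimal | time_limit | infeasible | unbounded | error
    diagnostics: list[str] = field(default_factory=list)

    @property
    def is_feasible(self) -> bool:
        return self.status in ("optimal", "time_limit") and np.isfinite(self.objective)


def build_model(grouped: GroupedInstance, config: MIPConfig | None = None) -> MIP:
    """Assemble the grouped MIP as sparse constraint matrices."""
    inst = grouped.instance
    n, nv = grouped.n_centers, grouped.n_vehicles
    if n < 2 or nv == 0:
        raise BuildError(f"need >= 2 centers and >= 1 vehicle, got {n} centers, {nv} vehicles")
    if config is None:
        config = MIPConfig.for_instance(grouped)
    o = grouped.depot
    l = inst.parameters.max_route_hours
    w = inst.parameters.dropoff_time
    h = grouped.transit
    avail = inst.roads.availability
    demand = np.stack([grouped.cold_volume, grouped.dry_volume], axis=1)  # (n, 2)

    nvars = count_variables(n, nv)
    model = MIP(
        grouped=grouped,
        config=config,
        c=np.zeros(nvars),
        A=sparse.csc_matrix((0, nvars)),
        lb=np.empty(0),
        ub=np.empty(0),
        var_lb=np.zeros(nvars),
        var_ub=np.full(nvars, np.inf),
        integrality=np.zeros(nvars),
    )
    iy, ix, it = model.iy, model.ix, model.it

    # objective: arc costs on y only
    cost = arc_cost_matrix(grouped, config.objective_form)
    for v in range(nv):
        for i in range(n):
            for j in range(n):
                model.c[iy(i, j, v)] = cost[i, j, v]

    # variable bounds
    for v in range(nv):
        for i in range(n):
            for j in range(n):
                k = iy(i, j, v)
                model.integrality[k] = 1
                # no self-arcs; only available arcs
                model.var_ub[k] = 0.0 if (i == j or avail[i, j] == 0) else 1.0
                for p in range(2):
                    model.var_ub[ix(i, j, v, p)] = config.m_flow[p]
        for i in range(n):
            model.var_ub[it(i, v)] = l

    rows: list[dict[int, float]] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add(row: dict[int, float], lo: float, hi: float) -> None:
        rows.append(row)
        lbs.append(lo)
        ubs.append(hi)

    # flow conservation: inflow - outflow = demand, at every center but the depot
    for p in range(2):
        for j in range(n):
            if j == o:
                continue
            row: dict[int, float] = {}
            for v in range(nv):
                for i in range(n):
                    if i == j:
                        continue
                    row[ix(i, j, v, p)] = row.get(ix(i, j, v, p), 0.0) + 1.0
                    row[ix(j, i, v, p)] = row.get(ix(j, i, v, p), 0.0) - 1.0
            add(row, demand[j, p], demand[j, p])

    # initial cold/dry loads within vehicle capacity
    caps = [
        [veh.cold_capacity for veh in inst.vehicles],
        [veh.dry_capacity for veh in inst.vehicles],
    ]
    for p in range(2):
        for v in range(nv):
            row = {ix(o, j, v, p): 1.0 for j in range(n) if j != o}
            add(row, -np.inf, caps[p][v])

    # time propagation on used arcs:  t_j - t_i - M y_ij >= h + W - M
    m_t = config.m_time
    for v in range(nv):
        for j in range(n):
            if j == o:
                continue
            for i in range(n):
                if i == j:
                    continue
                row = {it(j, v): 1.0, it(i, v): -1.0, iy(i, j, v): -m_t}
                add(row, h[i, j, v] + w - m_t, np.inf)

    # guaranteed depot return within the route limit:
    #   t_i + W (1 - y_{i,o}) + y_{i,j} (h_ij + h_jo) <= l
    for v in range(nv):
        for i in range(n):
            for j in range(n):
                row = {it(i, v): 1.0}
                row[iy(i, o, v)] = row.get(iy(i, o, v), 0.0) - w
                key = iy(i, j, v)
                row[key] = row.get(key, 0.0) + h[i, j, v] + h[j, o, v]
                add(row, -np.inf, l - w)

    # a vehicle is used only if it departs the depot (arc count linking)
    for v in range(nv):
        row = {}
        for i in range(n):
            for j in range(n):
                row[iy(i, j, v)] = row.get(iy(i, j, v), 0.0) + 1.0
        for j in range(n):
            row[iy(o, j, v)] = row.get(iy(o, j, v), 0.0) - config.m_count
        add(row, -np.inf, 0.0)

    # flow moves only if it departs the depot (flow linking)
    for p in range(2):
        for v in range(nv):
            row = {}
            for i in range(n):
                for j in range(n):
                    row[ix(i, j, v, p)] = row.get(ix(i, j, v, p), 0.0) + 1.0
            for j in range(n):
                row[ix(o, j, v, p)] = row.get(ix(o, j, v, p), 0.0) - config.m_flow[p]
            add(row, -np.inf, 0.0)

    # degree balance: a vehicle entering a center leaves it
    for v in range(nv):
        for j in range(n):
            row = {}
            for i in range(n):
                if i == j:
                    continue
                row[iy(i, j, v)] = row.get(iy(i, j, v), 0.0) + 1.0
                row[iy(j, i, v)] = row.get(iy(j, i, v), 0.0) - 1.0
            add(row, 0.0, 0.0)

    # flow only on used arcs:  M y_ij - x_ijp >= 0
    for p in range(2):
        for v in range(nv):
            for i in range(n):
                for j in range(n):
                    add({iy(i, j, v): config.m_flow[p], ix(i, j, v, p): -1.0}, 0.0, np.inf)

    # assemble sparse matrix
    data, ri, ci = [], [], []
    for r, row in enumerate(rows):
        for cidx, coef in row.items():
            ri.append(r)
            ci.append(cidx)
            data.append(coef)
    model.A = sparse.csc_matrix((data, (ri, ci)), shape=(len(rows), nvars))
    model.lb = np.array(lbs)
    model.ub = np.array(ubs)
    return model


_STATUS = {0: "optimal", 1: "time_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


def solve_mip(model: MIP) -> MIPSolution:
    """Solve the assembled model; returns incumbent, bound, gap and status."""
    cfg = model.config
    if cfg.backend != "highs":
        raise EnvironmentError(f"unknown solver backend {cfg.backend!r}")
    res = milp(
        c=model.c,
        constraints=LinearConstraint(model.A, model.lb, model.ub),
        integrality=model.integrality,
        bounds=Bounds(model.var_lb, model.var_ub),
        options={"time_limit": cfg.time_limit, "mip_rel_gap": cfg.mip_rel_gap},
    )
    status = _STATUS.get(res.status, "error")
    grouped = model.grouped
    n, nv = grouped.n_centers, grouped.n_vehicles
    diagnostics: list[str] = []
    if status == "infeasible":
        diagnostics = _infeasibility_diagnostics(grouped)
        return MIPSolution(
            y=np.zeros((n, n, nv)),
            x=np.zeros((n, n, nv, 2)),
            t=np.zeros((n, nv)),
            objective=np.inf,
            bound=np.inf,
            gap=np.inf,
            status=status,
            diagnostics=diagnostics,
        )
    if res.x is None:
        return MIPSolution(
            y=np.zeros((n, n, nv)),
            x=np.zeros((n, n, nv, 2)),
            t=np.zeros((n, nv)),
            objective=np.inf,
            bound=float(res.mip_dual_bound) if res.mip_dual_bound is not None else -np.inf,
            gap=np.inf,
            status=status,
            diagnostics=[res.message or "no incumbent"],
        )
    xfull = np.asarray(res.x)
    y = np.zeros((n, n, nv))
    x = np.zeros((n, n, nv, 2))
    t = np.zeros((n, nv))
    for v in range(nv):
        for i in range(n):
            t[i, v] = xfull[model.it(i, v)]
            for j in range(n):
                y[i, j, v] = round(xfull[model.iy(i, j, v)])
                for p in range(2):
                    x[i, j, v, p] = xfull[model.ix(i, j, v, p)]
    obj = float(res.fun)
    bound = float(res.mip_dual_bound) if res.mip_dual_bound is not None else obj
    gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    return MIPSolution(y=y, x=x, t=t, objective=obj, bound=bound, gap=gap, status=status)


def _infeasibility_diagnostics(grouped: GroupedInstance) -> list[str]:
    """Name structural causes of infeasibility where detectable."""
    inst = grouped.instance
    o = grouped.depot
    avail = inst.roads.availability
    l = inst.parameters.max_route_hours
    w = inst.parameters.dropoff_time
    out = []
    for j in grouped.demanded_centers():
        name = inst.centers[j].name
        if avail[o, j] == 0 and all(avail[i, j] == 0 for i in range(grouped.n_centers) if i != j):
            out.append(f"center {name!r} has no available inbound road")
            continue
        fits = any(
            grouped.cold_volume[j] <= v.cold_capacity + 1e-9
            and grouped.dry_volume[j] <= v.dry_capacity + 1e-9
            for v in inst.vehicles
        )
        if not fits:
            out.append(f"demand volume at center {name!r} exceeds every vehicle capacity")
        if avail[o, j] and avail[j, o]:
            quickest = min(
                grouped.transit[o, j, v] + w + grouped.transit[j, o, v]
                for v in range(grouped.n_vehicles)
            )
            if quickest > l + 1e-9:
                out.append(
                    f"center {name!r} cannot be visited within the {l} h route limit"
                )
    if not out:
        out.append("model infeasible; no single-center structural cause identified")
    return out


def extract_routes(mip_solution: MIPSolution, grouped: GroupedInstance) -> Solution:
    """Turn y/x/t values into depot-rooted routes with deliveries.

    Arcs of each vehicle are walked from the depot following increasing
    departure times; any arc left over (a cycle avoiding the depot) raises
    :class:`SolutionIntegrityError`, since the time-propagation constraints
    make such cycles impossible in a correct model.
    """
    if not mip_solution.is_feasible:
        raise SolutionIntegrityError(f"no feasible solution to extract (status {mip_solution.status})")
    n, nv = grouped.n_centers, grouped.n_vehicles
    o = grouped.depot
    h = grouped.transit
    w = grouped.instance.parameters.dropoff_time
    routes: list[Route] = []
    for v in range(nv):
        arcs = {(i, j) for i in range(n) for j in range(n) if mip_solution.y[i, j, v] > 0.5}
        used: set[tuple[int, int]] = set()
        while True:
            starts = sorted(
                (j for (i, j) in arcs - used if i == o),
                key=lambda j: (mip_solution.t[j, v], j),
            )
            if not starts:
                break
            stops = [o]
            departures = [float(mip_solution.t[o, v])]
            cur = o
            nxt = starts[0]
            used.add((o, nxt))
            while nxt != o:
                stops.append(nxt)
                departures.append(float(mip_solution.t[nxt, v]))
                cur = nxt
                outs = sorted(
                    (j for (i, j) in arcs - used if i == cur),
                    key=lambda j: (mip_solution.t[j, v] if j != o else np.inf, j),
                )
                if not outs:
                    raise SolutionIntegrityError(
                        f"vehicle {v}: route stranded at center {cur} (degree imbalance)"
                    )
                nxt = outs[0]
                used.add((cur, nxt))
            stops.append(o)
            arrival = departures[-1] + float(h[cur, o, v])
            deliveries = {}
            for jj in stops[1:-1]:
                cold = float(mip_solution.x[:, jj, v, 0].sum() - mip_solution.x[jj, :, v, 0].sum())
                dry = float(mip_solution.x[:, jj, v, 1].sum() - mip_solution.x[jj, :, v, 1].sum())
                deliveries[jj] = (max(cold, 0.0), max(dry, 0.0))
            routes.append(
                Route(vehicle=v, stops=stops, departures=departures, arrival=arrival, deliveries=deliveries)
            )
        if arcs - used:
            raise SolutionIntegrityError(
                f"vehicle {v}: arcs {sorted(arcs - used)} form a cycle not through the depot"
            )
    return Solution(
        routes=routes,
        objective=mip_solution.objective,
        bound=mip_solution.bound,
        gap=mip_solution.gap,
        status=mip_solution.status,
        solver="mip",
    )
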