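"""Two-stage index-rule solver with elite-set branch-and-bound.

Construction works in two stages.  First a vehicle is chosen by a vehicle
index that prefers low penalty, large cold/dry capacity and high velocity:

    e^(-beta_v/mu_beta) + e^(c_vr/mu_cr) + e^(c_vd/mu_cd) + e^(v_v/mu_v)

Then the chosen vehicle's route is grown one center at a time, always adding
the *feasible* unserved center with the largest node index

    W_t e^(-h_ijv/mu_h) + W_p e^(-gamma_ij/mu_gamma)

which prefers nearby centers on low-penalty roads.  Feasibility of an
extension requires an available road, enough remaining cold and dry
capacity, and enough time to drop off and still return to the depot within
the route limit.  When no center fits, the route closes and the next
vehicle (by index order) opens a route; every vehicle gets a turn before
any vehicle is reused.

The branch-and-bound wraps this construction: each feasible first-center
choice of the top-indexed vehicle roots one branch (plus one branch that
skips that vehicle, so fleets can be left partially idle).  Each branch is
greedily completed to an incumbent; an elite subset (12%, half best
incumbents, half largest uncertainty intervals) is explored depth-first
first, children in decreasing node-index order, pruning with committed cost
plus a minimum-spanning-tree lower bound over the unserved centers.  With
an uncapped budget the search is exhaustive and therefore exact.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .instance import ScalingMeans, Vehicle
from .objective import Route, Solution, arc_cost_matrix
from .preprocess import GroupedInstance


class InfeasibleRoutingError(RuntimeError):
    """No vehicle can serve some demanded center(s)."""

    def __init__(self, center_names: list[str]):
        self.center_names = center_names
        super().__init__(
            "no vehicle can serve center(s): " + ", ".join(repr(c) for c in center_names)
        )


def _safe_exp(value: float, mean: float, sign: float) -> float:
    return math.exp(sign * (value / mean if mean != 0 else 0.0))


def vehicle_index(vehicle: Vehicle, means: ScalingMeans) -> float:
    """Stage-1 score; the largest-index vehicle is routed first."""
    return (
        _safe_exp(vehicle.penalty, means.mu_beta, -1.0)
        + _safe_exp(vehicle.cold_capacity, means.mu_cr, 1.0)
        + _safe_exp(vehicle.dry_capacity, means.mu_cd, 1.0)
        + _safe_exp(vehicle.velocity, means.mu_v, 1.0)
    )


def node_index(grouped: GroupedInstance, i: int, j: int, v: int) -> float:
    """Stage-2 score for extending a route from i to j with vehicle v."""
    m = grouped.means
    return grouped.w_transit * _safe_exp(
        grouped.transit[i, j, v], m.mu_h, -1.0
    ) + grouped.w_penalty * _safe_exp(
        float(grouped.instance.roads.penalty[i, j]), m.mu_gamma, -1.0
    )


def _node_index_matrix(grouped: GroupedInstance) -> np.ndarray:
    """node_index for all (i, j, v); greedy ranking is form-independent."""
    m = grouped.means
    ih = grouped.transit / m.mu_h if m.mu_h else np.zeros_like(grouped.transit)
    ig = (
        grouped.instance.roads.penalty / m.mu_gamma
        if m.mu_gamma
        else np.zeros_like(grouped.instance.roads.penalty)
    )
    return grouped.w_transit * np.exp(-ih) + grouped.w_penalty * np.exp(-ig)[:, :, None]


def vehicle_order(grouped: GroupedInstance) -> list[int]:
    """Vehicles sorted by decreasing vehicle index; ties by input order."""
    scores = [vehicle_index(v, grouped.means) for v in grouped.instance.vehicles]
    return sorted(range(len(scores)), key=lambda v: (-scores[v], v))


@dataclass(frozen=True)
class RouteState:
    """An open (not yet closed) route for one vehicle."""

    vehicle: int
    stops: tuple[int, ...]  # starts at the depot
    departures: tuple[float, ...]  # departure time at each stop so far
    time: float  # departure time at the last stop
    rem_cold: float
    rem_dry: float

    @property
    def last(self) -> int:
        return self.stops[-1]

    @property
    def is_empty(self) -> bool:
        return len(self.stops) == 1


def _fresh_state(grouped: GroupedInstance, v: int) -> RouteState:
    veh = grouped.instance.vehicles[v]
    return RouteState(
        vehicle=v,
        stops=(grouped.depot,),
        departures=(0.0,),
        time=0.0,
        rem_cold=veh.cold_capacity,
        rem_dry=veh.dry_capacity,
    )


def feasible_extension(
    state: RouteState, j: int, grouped: GroupedInstance
) -> tuple[bool, str]:
    """Can the open route visit center j next?  Returns (flag, reason).

    Checks, in order: road availability from the current endpoint (and of
    the eventual return leg j -> depot, without which the route would be
    stranded), remaining cold then dry capacity, and the time to reach j,
    drop off, and still get back to the depot within the route limit.
    """
    inst = grouped.instance
    o = grouped.depot
    v = state.vehicle
    tol = grouped.config.feasibility_tol
    if inst.roads.availability[state.last, j] == 0:
        return False, "road unavailable"
    if inst.roads.availability[j, o] == 0:
        return False, "return road unavailable"
    if grouped.cold_volume[j] > state.rem_cold + tol:
        return False, "cold capacity exceeded"
    if grouped.dry_volume[j] > state.rem_dry + tol:
        return False, "dry capacity exceeded"
    w = inst.parameters.dropoff_time
    l = inst.parameters.max_route_hours
    if (
        state.time + grouped.transit[state.last, j, v] + w + grouped.transit[j, o, v]
        > l + tol
    ):
        return False, "route time limit exceeded"
    return True, "ok"


def _extend(state: RouteState, j: int, grouped: GroupedInstance) -> RouteState:
    v = state.vehicle
    w = grouped.instance.parameters.dropoff_time
    new_time = state.time + float(grouped.transit[state.last, j, v]) + w
    return replace(
        state,
        stops=state.stops + (j,),
        departures=state.departures + (new_time,),
        time=new_time,
        rem_cold=state.rem_cold - float(grouped.cold_volume[j]),
        rem_dry=state.rem_dry - float(grouped.dry_volume[j]),
    )


def _close(state: RouteState, grouped: GroupedInstance) -> Route:
    o = grouped.depot
    arrival = state.time + float(grouped.transit[state.last, o, state.vehicle])
    return Route(
        vehicle=state.vehicle,
        stops=list(state.stops) + [o],
        departures=list(state.departures),
        arrival=arrival,
        deliveries={
            j: (float(grouped.cold_volume[j]), float(grouped.dry_volume[j]))
            for j in state.stops[1:]
        },
    )


def _route_cost(route_arcs, vehicle: int, cost: np.ndarray) -> float:
    return float(sum(cost[i, j, vehicle] for i, j in route_arcs))


# ---------------------------------------------------------------------------
# Greedy construction
# ---------------------------------------------------------------------------

def _greedy_from(
    grouped: GroupedInstance,
    order: list[int],
    state: RouteState | None,
    unserved: set[int],
    turn: int,
    nidx: np.ndarray,
    cost: np.ndarray,
) -> tuple[list[Route], float, list[tuple[int, bool]]] | None:
    """Greedy completion from a partial state; None if it gets stuck."""
    nv = len(order)
    routes: list[Route] = []
    turns: list[tuple[int, bool]] = []
    total = 0.0
    unserved = set(unserved)
    empties = 0
    while True:
        if state is None:
            if not unserved:
                break
            state = _fresh_state(grouped, order[turn % nv])
        # grow the open route
        while True:
            cands = [j for j in sorted(unserved) if feasible_extension(state, j, grouped)[0]]
            if not cands:
                break
            best = max(cands, key=lambda j: (nidx[state.last, j, state.vehicle], -j))
            total += cost[state.last, best, state.vehicle]
            state = _extend(state, best, grouped)
            unserved.discard(best)
        served_any = not state.is_empty
        if served_any:
            route = _close(state, grouped)
            total += cost[state.last, grouped.depot, state.vehicle]
            routes.append(route)
            empties = 0
        else:
            empties += 1
        turns.append((state.vehicle, served_any))
        state = None
        turn += 1
        if not unserved:
            break
        if empties >= nv:
            return None  # a full vehicle cycle made no progress
    return routes, total, turns


def construct_greedy(
    grouped: GroupedInstance, order: list[int] | None = None
) -> Solution:
    """Index-rule construction: a feasible solution, fast and deterministic."""
    order = order if order is not None else vehicle_order(grouped)
    nidx = _node_index_matrix(grouped)
    cost = arc_cost_matrix(grouped)
    unserved = set(grouped.demanded_centers())
    result = _greedy_from(grouped, order, None, unserved, 0, nidx, cost)
    if result is None:
        raise InfeasibleRoutingError(_unservable_names(grouped, unserved))
    routes, total, turns = result
    return Solution(
        routes=routes, objective=total, status="feasible", solver="greedy", turns=turns
    )


def _unservable_names(grouped: GroupedInstance, unserved: set[int]) -> list[str]:
    """Best-effort naming of centers no single-stop route can serve."""
    inst = grouped.instance
    names = []
    for j in sorted(unserved):
        ok = False
        for v in range(grouped.n_vehicles):
            st = _fresh_state(grouped, v)
            if feasible_extension(st, j, grouped)[0]:
                ok = True
                break
        if not ok:
            names.append(inst.centers[j].name)
    return names or [inst.centers[j].name for j in sorted(unserved)]


# ---------------------------------------------------------------------------
# MST lower bound
# ---------------------------------------------------------------------------

def _undirected_cost(grouped: GroupedInstance, cost: np.ndarray) -> np.ndarray:
    """Per-pair lower bound on any traversal cost: min over vehicles and
    directions of the arc cost, inf where no direction is available."""
    avail = grouped.instance.roads.availability.astype(bool)
    minv = cost.min(axis=2)
    directed = np.where(avail, minv, np.inf)
    und = np.minimum(directed, directed.T)
    np.fill_diagonal(und, np.inf)
    return und


def mst_lower_bound(
    nodes: list[int],
    grouped: GroupedInstance,
    und_cost: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Minimum-spanning-tree weight over ``nodes`` (center indices).

    Every feasible completion's arc set, viewed undirected, spans these
    nodes, and each arc costs at least the undirected pair cost, so the MST
    weight is a valid lower bound.  If the availability graph disconnects
    the set, the bound covers the depot's component only and the second
    return value is False.
    """
    if und_cost is None:
        und_cost = _undirected_cost(grouped, arc_cost_matrix(grouped))
    nodes = sorted(set(nodes))
    k = len(nodes)
    if k <= 1:
        return 0.0, True
    sub = und_cost[np.ix_(nodes, nodes)]
    finite = np.isfinite(sub)
    graph = csr_matrix(np.where(finite, sub, 0.0))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp == 1:
        tree = minimum_spanning_tree(graph)
        return float(tree.sum()), True
    # disconnected: bound over the component containing the depot (or the
    # first listed node if the depot is not in the set)
    anchor = nodes.index(grouped.depot) if grouped.depot in nodes else 0
    comp = labels == labels[anchor]
    if comp.sum() <= 1:
        return 0.0, False
    subsub = sub[np.ix_(np.where(comp)[0], np.where(comp)[0])]
    graph2 = csr_matrix(np.where(np.isfinite(subsub), subsub, 0.0))
    tree = minimum_spanning_tree(graph2)
    return float(tree.sum()), False


# ---------------------------------------------------------------------------
# Elite-set branch-and-bound
# ---------------------------------------------------------------------------

ELITE_FRACTION = 0.12


def elite_partition(n_branches: int) -> tuple[int, int]:
    """(n_best, n_uncertainty) elite slots for a given branch count.

    Elite size is ceil(0.12 * n), floored at 1; with at least two branches
    each half gets at least one slot.
    """
    if n_branches <= 0:
        return 0, 0
    size = max(1, math.ceil(ELITE_FRACTION * n_branches))
    if n_branches == 1:
        return 1, 0
    n_best = max(1, math.ceil(size / 2))
    n_unc = max(1, size - n_best)
    n_best = min(n_best, n_branches)
    n_unc = min(n_unc, n_branches - n_best)
    return n_best, n_unc


@dataclass
class SearchNode:
    """A branch-and-bound node: committed prefix plus one open route."""

    routes: tuple[Route, ...]
    open_state: RouteState | None
    unserved: frozenset[int]
    cost: float  # committed arc cost
    turn: int
    empties: int  # consecutive vehicle turns with no service
    turns: tuple[tuple[int, bool], ...]
    lower_bound: float = 0.0


@dataclass
class _Branch:
    label: int
    node: SearchNode
    incumbent_value: float
    incumbent: tuple[list[Route], list[tuple[int, bool]]] | None
    lower_bound: float

    @property
    def uncertainty(self) -> float:
        return self.incumbent_value - self.lower_bound


def branch_and_bound(
    grouped: GroupedInstance,
    budget_s: float = 120.0,
    quantum: int = 1000,
    node_limit: int | None = None,
) -> Solution:
    """Anytime exact search: never worse than the greedy construction, exact
    when the budget allows full exploration.

    Returns the best incumbent with a global lower bound and gap.
    """
    inst = grouped.instance
    order = vehicle_order(grouped)
    nv = len(order)
    o = grouped.depot
    nidx = _node_index_matrix(grouped)
    cost = arc_cost_matrix(grouped)
    und = _undirected_cost(grouped, cost)
    demanded = grouped.demanded_centers()
    if not demanded:
        return Solution(routes=[], objective=0.0, bound=0.0, gap=0.0, solver="bnb")

    greedy = construct_greedy(grouped, order)
    best_value = greedy.objective
    best_routes = greedy.routes
    best_turns = greedy.turns
    warnings: list[str] = []

    root_bound, connected = mst_lower_bound([o] + demanded, grouped, und)
    if not connected:
        warnings.append("availability graph is disconnected; bound covers the depot component")

    tol = 1e-9

    def node_bound(node: SearchNode) -> float:
        endpoint = node.open_state.last if node.open_state is not None else o
        sub, _ = mst_lower_bound([o, endpoint, *node.unserved], grouped, und)
        return node.cost + sub

    def children(node: SearchNode) -> list[SearchNode]:
        out: list[SearchNode] = []
        state = node.open_state
        assert state is not None
        v = state.vehicle
        # closing (or skipping) the vehicle's turn comes last in DFS order
        served_any = not state.is_empty
        if served_any or node.empties + 1 < nv:
            new_cost = node.cost
            new_routes = node.routes
            if served_any:
                new_cost += cost[state.last, o, v]
                new_routes = node.routes + (_close(state, grouped),)
            nturn = node.turn + 1
            nempt = 0 if served_any else node.empties + 1
            nxt = (
                _fresh_state(grouped, order[nturn % nv]) if node.unserved else None
            )
            out.append(
                SearchNode(
                    routes=new_routes,
                    open_state=nxt,
                    unserved=node.unserved,
                    cost=new_cost,
                    turn=nturn,
                    empties=nempt,
                    turns=node.turns + ((v, served_any),),
                )
            )
        exts = [
            j for j in sorted(node.unserved) if feasible_extension(state, j, grouped)[0]
        ]
        # best node-index last in the list => popped first from the stack
        exts.sort(key=lambda j: (nidx[state.last, j, v], -j))
        for j in exts:
            out.append(
                SearchNode(
                    routes=node.routes,
                    open_state=_extend(state, j, grouped),
                    unserved=node.unserved - {j},
                    cost=node.cost + cost[state.last, j, v],
                    turn=node.turn,
                    empties=node.empties,
                    turns=node.turns,
                )
            )
        return out

    def try_finish(node: SearchNode) -> None:
        """Node with all demand served: close the open route, score it."""
        nonlocal best_value, best_routes, best_turns
        total = node.cost
        routes = list(node.routes)
        turns = list(node.turns)
        state = node.open_state
        if state is not None and not state.is_empty:
            total += cost[state.last, o, state.vehicle]
            routes.append(_close(state, grouped))
            turns.append((state.vehicle, True))
        if total < best_value - tol:
            best_value = total
            best_routes = routes
            best_turns = turns

    def greedy_completion(node: SearchNode):
        res = _greedy_from(
            grouped,
            order,
            node.open_state,
            set(node.unserved),
            node.turn,
            nidx,
            cost,
        )
        if res is None:
            return None
        routes, added, turns = res
        return list(node.routes) + routes, node.cost + added, list(node.turns) + turns

    # --- initial branches: first-center choices of the top-indexed vehicle,
    # --- plus one branch that gives the top vehicle an empty turn
    root_state = _fresh_state(grouped, order[0])
    branches: list[_Branch] = []
    firsts = [j for j in sorted(demanded) if feasible_extension(root_state, j, grouped)[0]]
    firsts.sort(key=lambda j: (-nidx[o, j, order[0]], j))
    roots: list[SearchNode] = [
        SearchNode(
            routes=(),
            open_state=_extend(root_state, j, grouped),
            unserved=frozenset(demanded) - {j},
            cost=float(cost[o, j, order[0]]),
            turn=0,
            empties=0,
            turns=(),
        )
        for j in firsts
    ]
    if nv > 1:
        roots.append(
            SearchNode(
                routes=(),
                open_state=_fresh_state(grouped, order[1 % nv]),
                unserved=frozenset(demanded),
                cost=0.0,
                turn=1,
                empties=1,
                turns=((order[0], False),),
            )
        )
    for label, node in enumerate(roots):
        comp = greedy_completion(node)
        inc_val = comp[1] if comp is not None else math.inf
        lb = node_bound(node)
        node.lower_bound = lb
        branches.append(
            _Branch(
                label=label,
                node=node,
                incumbent_value=inc_val,
                incumbent=(comp[0], comp[2]) if comp is not None else None,
                lower_bound=lb,
            )
        )
        if comp is not None and inc_val < best_value - tol:
            best_value, best_routes, best_turns = inc_val, comp[0], comp[2]

    # --- elite selection
    n_best, n_unc = elite_partition(len(branches))
    by_value = sorted(branches, key=lambda b: (b.incumbent_value, b.label))
    elite = by_value[:n_best]
    rest = [b for b in branches if b not in elite]
    rest.sort(key=lambda b: (-b.uncertainty, b.label))
    elite += rest[:n_unc]
    non_elite = [b for b in by_value if b not in elite]

    # --- depth-first exploration, elite branches first, round-robin
    deadline = time.monotonic() + budget_s
    stacks: list[list[SearchNode]] = [[b.node] for b in elite + non_elite]
    expansions = 0
    out_of_budget = False
    active = list(range(len(stacks)))
    while active and not out_of_budget:
        next_active: list[int] = []
        for si in active:
            stack = stacks[si]
            quota = quantum
            while stack and quota > 0:
                if time.monotonic() > deadline or (
                    node_limit is not None and expansions >= node_limit
                ):
                    out_of_budget = True
                    break
                node = stack.pop()
                quota -= 1
                expansions += 1
                if node.lower_bound >= best_value - tol:
                    continue
                if not node.unserved:
                    try_finish(node)
                    continue
                if node.open_state is None:
                    node = replace(
                        node, open_state=_fresh_state(grouped, order[node.turn % nv])
                    )
                for child in children(node):
                    child.lower_bound = node_bound(child)
                    if child.lower_bound < best_value - tol:
                        stack.append(child)
            if out_of_budget:
                break
            if stack:
                next_active.append(si)
        active = next_active

    open_bounds = [nd.lower_bound for st in stacks for nd in st]
    if open_bounds:
        bound = max(root_bound, min(open_bounds))
        bound = min(bound, best_value)
    else:
        bound = best_value
    return Solution(
        routes=best_routes,
        objective=best_value,
        bound=bound,
        gap=best_value - bound,
        status="optimal" if not open_bounds else "feasible",
        solver="bnb",
        turns=best_turns,
        warnings=warnings,
    )
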