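"""Independent brute-force oracle for small routing instances.

Enumerates every assignment of demanded centers to vehicles and every visit
order, evaluating feasibility (availability, cold/dry capacity, route time
limit) and the arc-cost objective from first principles — sharing no route
construction or search code with the package solvers.
"""

import itertools
import math


def _arc_cost(h, gamma, beta, wt, wp, means, form):
    sign = -1.0 if form == "printed" else 1.0
    e = lambda val, mu: math.exp(sign * (val / mu if mu else 0.0))
    return wt * e(h, means.mu_h) + wp * (e(gamma, means.mu_gamma) + e(beta, means.mu_beta))


def brute_force_optimum(grouped, objective_form=None):
    """Minimum objective over all single-visit routing plans, or inf if none
    is feasible."""
    inst = grouped.instance
    form = objective_form or grouped.config.objective_form
    o = grouped.depot
    nv = grouped.n_vehicles
    avail = inst.roads.availability
    l = inst.parameters.max_route_hours
    w = inst.parameters.dropoff_time
    means = grouped.means
    gamma = inst.roads.penalty
    dist = inst.roads.distance

    def route_cost(order, v):
        veh = inst.vehicles[v]
        if sum(grouped.cold_volume[j] for j in order) > veh.cold_capacity + 1e-9:
            return None
        if sum(grouped.dry_volume[j] for j in order) > veh.dry_capacity + 1e-9:
            return None
        t, cur, c = 0.0, o, 0.0
        for j in order:
            if not avail[cur, j] or not avail[j, o]:
                return None
            t += dist[cur, j] / veh.velocity + w
            if t + dist[j, o] / veh.velocity > l + 1e-9:
                return None
            c += _arc_cost(
                dist[cur, j] / veh.velocity, gamma[cur, j], veh.penalty,
                grouped.w_transit, grouped.w_penalty, means, form,
            )
            cur = j
        c += _arc_cost(
            dist[cur, o] / veh.velocity, gamma[cur, o], veh.penalty,
            grouped.w_transit, grouped.w_penalty, means, form,
        )
        return c

    items = sorted(grouped.demanded_centers())
    best = math.inf
    cache: dict[tuple[int, frozenset], float | None] = {}

    def best_route(sub, v):
        key = (v, frozenset(sub))
        if key not in cache:
            cache[key] = min(
                (rc for perm in itertools.permutations(sub)
                 if (rc := route_cost(perm, v)) is not None),
                default=None,
            )
        return cache[key]

    for assign in itertools.product(range(nv), repeat=len(items)):
        total, ok = 0.0, True
        for v in range(nv):
            sub = tuple(j for j, a in zip(items, assign) if a == v)
            if not sub:
                continue
            bc = best_route(sub, v)
            if bc is None:
                ok = False
                break
            total += bc
        if ok and total < best:
            best = total
    return best
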