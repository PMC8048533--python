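"""Arc costs and solution containers shared by the MIP and the index solver.

The objective is a weighted sum over used arcs (i, j, v) of an exponential
transit-time term and exponential road/vehicle penalty terms, each scaled by
its instance-level mean:

    printed form:    W_t e^(-h/mu_h) + W_p (e^(-gamma/mu_gamma) + e^(-beta/mu_beta))
    increasing form: W_t e^(+h/mu_h) + W_p (e^(+gamma/mu_gamma) + e^(+beta/mu_beta))

Both are strictly positive, so every extra arc adds cost and minimization
never adds idle arcs.  The printed form is decreasing in time and penalty
(cheap arcs are the long/risky ones); the increasing form restores the
intuitive direction.  Both are first-class; "printed" is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instance import ScalingMeans
from .preprocess import GroupedInstance


def _safe_ratio(value: float | np.ndarray, mean: float) -> float | np.ndarray:
    """value/mean with a 0 fallback for degenerate (zero) means."""
    if mean == 0:
        return np.zeros_like(np.asarray(value, dtype=float))
    return np.asarray(value, dtype=float) / mean


def arc_cost(
    h: float,
    gamma: float,
    beta: float,
    w_transit: float,
    w_penalty: float,
    means: ScalingMeans,
    objective_form: str = "printed",
) -> float:
    """Cost contribution of one arc (i, j) traversed by vehicle v."""
    sign = -1.0 if objective_form == "printed" else 1.0
    return float(
        w_transit * np.exp(sign * _safe_ratio(h, means.mu_h))
        + w_penalty
        * (
            np.exp(sign * _safe_ratio(gamma, means.mu_gamma))
            + np.exp(sign * _safe_ratio(beta, means.mu_beta))
        )
    )


def arc_cost_matrix(grouped: GroupedInstance, objective_form: str | None = None) -> np.ndarray:
    """Arc costs for all (i, j, v), shape (n, n, |V|)."""
    form = objective_form or grouped.config.objective_form
    sign = -1.0 if form == "printed" else 1.0
    m = grouped.means
    h = grouped.transit  # (n, n, nv)
    gamma = grouped.instance.roads.penalty  # (n, n)
    beta = np.array([v.penalty for v in grouped.instance.vehicles])
    cost = grouped.w_transit * np.exp(sign * _safe_ratio(h, m.mu_h))
    cost = cost + grouped.w_penalty * (
        np.exp(sign * _safe_ratio(gamma, m.mu_gamma))[:, :, None]
        + np.exp(sign * _safe_ratio(beta, m.mu_beta))[None, None, :]
    )
    return cost


@dataclass
class Route:
    """One closed vehicle route: depot -> centers -> depot.

    ``stops`` holds center indices including the depot at both ends.
    ``departures`` holds the departure time (hours from route start) at each
    stop except the final depot arrival; ``arrival`` is the time back at the
    depot.  ``deliveries`` maps center index -> (cold liters, dry liters).
    """

    vehicle: int
    stops: list[int]
    departures: list[float]
    arrival: float
    deliveries: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def arcs(self) -> list[tuple[int, int]]:
        return list(zip(self.stops[:-1], self.stops[1:]))

    @property
    def visited(self) -> list[int]:
        return self.stops[1:-1]

    def cold_load(self) -> float:
        return sum(c for c, _ in self.deliveries.values())

    def dry_load(self) -> float:
        return sum(d for _, d in self.deliveries.values())


@dataclass
class Solution:
    """A complete routing plan with objective value and (optional) bound."""

    routes: list[Route]
    objective: float
    bound: float | None = None
    gap: float | None = None
    status: str = "feasible"
    solver: str = ""
    # vehicle turn sequence as taken by the heuristic cycle, entries
    # (vehicle, served_any); used to audit the all-vehicles-before-reuse rule
    turns: list[tuple[int, bool]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_routes(self) -> int:
        return len(self.routes)


def solution_cost(
    solution_or_routes: Solution | list[Route],
    grouped: GroupedInstance,
    objective_form: str | None = None,
) -> float:
    """Objective value of a set of routes: sum of arc costs over all legs."""
    routes = (
        solution_or_routes.routes
        if isinstance(solution_or_routes, Solution)
        else solution_or_routes
    )
    cost = arc_cost_matrix(grouped, objective_form)
    total = 0.0
    for r in routes:
        for i, j in r.arcs:
            total += cost[i, j, r.vehicle]
    return float(total)
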