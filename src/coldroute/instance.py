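"""Domain model of a district routing instance.

A district instance describes one delivery problem: a set of health centers
(one of which is the depot / supply node), the products to distribute
(classified cold vs dry), the vehicle fleet with separate cold-box and dry
carrying capacities, an asymmetric road network with categorical road
conditions, a per-center per-product demand table, and run parameters
(route time limit, drop-off time, objective weights).

Units are fixed throughout the package: volumes in liters, times in hours,
distances in km, velocities in km/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .config import (
    Config,
    DEFAULT_CONFIG,
    ROAD_CONDITION_LABELS,
    VEHICLE_CONDITION_LABELS,
)


class LookupError_(KeyError):
    """Unknown center / vehicle / product name."""


class DegenerateInstanceError(ValueError):
    """Instance has no centers or no vehicles where some are required."""


@dataclass(frozen=True)
class Center:
    name: str
    center_type: str = "health center"
    cold_capacity: float = 0.0  # liters
    dry_capacity: float = 0.0  # liters
    is_depot: bool = False


@dataclass(frozen=True)
class Product:
    name: str
    unit_volume: float  # liters per dose/unit (k_p)
    doses_per_vial: int = 1
    requires_cold: bool = False
    available_supply: float = float("inf")  # units available at the depot


@dataclass(frozen=True)
class Vehicle:
    name: str
    condition_class: str  # one of the 4 ordered reliability labels
    penalty: float  # beta_v, derived from condition_class
    velocity: float  # km/h
    cold_capacity: float  # liters
    dry_capacity: float  # liters
    fuel_consumption: float = 0.0  # liters per km
    fuel_price: float = 0.0  # currency per liter
    per_diem: float = 0.0  # currency per route-day


@dataclass(frozen=True)
class RoadNetwork:
    """Asymmetric distances plus categorical conditions between centers.

    ``penalty`` (gamma_ij) and ``availability`` (a_ij) are derived from the
    condition labels when the network is built; unavailable arcs and the
    diagonal carry penalty 0 (they are never traversed).
    """

    distance: np.ndarray  # km, shape (n, n)
    condition: np.ndarray  # labels, shape (n, n), dtype object/str
    penalty: np.ndarray  # gamma_ij >= 0
    availability: np.ndarray  # a_ij in {0, 1}

    @staticmethod
    def from_labels(
        distance: np.ndarray, condition: np.ndarray, config: Config = DEFAULT_CONFIG
    ) -> "RoadNetwork":
        distance = np.asarray(distance, dtype=float)
        condition = np.asarray(condition, dtype=object)
        n = distance.shape[0]
        if distance.shape != (n, n) or condition.shape != (n, n):
            raise ValueError("distance and condition must be square and congruent")
        penalty = np.zeros((n, n))
        avail = np.ones((n, n), dtype=int)
        for i in range(n):
            for j in range(n):
                label = condition[i, j]
                if label not in ROAD_CONDITION_LABELS:
                    raise ValueError(f"unknown road condition label {label!r} at ({i},{j})")
                if label == "not accessible":
                    avail[i, j] = 0
                elif i != j:
                    penalty[i, j] = config.road_penalties[label]
        return RoadNetwork(distance, condition, penalty, avail)


@dataclass(frozen=True)
class Parameters:
    run_description: str = ""
    start_location: str = ""  # depot center name
    start_time: str = "08:00"  # clock time HH:MM
    max_route_hours: float = 8.0  # l
    dropoff_time: float = 0.25  # W, hours spent at each visited center
    transit_weight_raw: float = 5.0  # user weight in [0, 10]

    @property
    def weights(self) -> tuple[float, float]:
        """(W_t, W_p) normalized to [0, 1] with W_t + W_p = 1."""
        from .preprocess import normalize_weights

        return normalize_weights(self.transit_weight_raw)


@dataclass(frozen=True)
class ScalingMeans:
    """Instance-level averages used to put objective terms on one scale."""

    mu_h: float  # mean transit time (hours)
    mu_gamma: float  # mean road penalty
    mu_beta: float  # mean vehicle penalty
    mu_cr: float  # mean cold capacity (liters)
    mu_cd: float  # mean dry capacity (liters)
    mu_v: float  # mean velocity (km/h)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning" | "info"
    message: str


@dataclass
class Instance:
    """A full district description; the unit of input to the pipeline."""

    centers: list[Center]
    products: list[Product]
    vehicles: list[Vehicle]
    roads: RoadNetwork
    demand: np.ndarray  # units, shape (n_centers, n_products)
    parameters: Parameters = field(default_factory=Parameters)

    # --- indexing helpers -------------------------------------------------
    @property
    def n_centers(self) -> int:
        return len(self.centers)

    @property
    def center_names(self) -> list[str]:
        return [c.name for c in self.centers]

    @property
    def product_names(self) -> list[str]:
        return [p.name for p in self.products]

    @property
    def vehicle_names(self) -> list[str]:
        return [v.name for v in self.vehicles]

    def center_index(self, name: str) -> int:
        try:
            return self.center_names.index(name)
        except ValueError:
            raise LookupError_(f"unknown center {name!r}") from None

    def vehicle_index_of(self, name: str) -> int:
        try:
            return self.vehicle_names.index(name)
        except ValueError:
            raise LookupError_(f"unknown vehicle {name!r}") from None

    @property
    def depot(self) -> int:
        """Index of the depot center (supply node o)."""
        for i, c in enumerate(self.centers):
            if c.is_depot:
                return i
        raise DegenerateInstanceError("instance has no depot center")


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def transit_time(instance: Instance, i: int | str, j: int | str, v: int | str) -> float:
    """Transit time h_ijv (hours) = distance_ij / velocity_v; 0 when i == j."""
    ii = instance.center_index(i) if isinstance(i, str) else i
    jj = instance.center_index(j) if isinstance(j, str) else j
    vv = instance.vehicle_index_of(v) if isinstance(v, str) else v
    n = instance.n_centers
    if not (0 <= ii < n and 0 <= jj < n):
        raise LookupError_(f"center index out of range: {i!r}, {j!r}")
    if not 0 <= vv < len(instance.vehicles):
        raise LookupError_(f"vehicle index out of range: {v!r}")
    if ii == jj:
        return 0.0
    return float(instance.roads.distance[ii, jj]) / instance.vehicles[vv].velocity


def transit_time_matrix(instance: Instance) -> np.ndarray:
    """h_ijv for all (i, j, v), shape (n, n, |V|); diagonal is zero."""
    dist = instance.roads.distance.astype(float).copy()
    np.fill_diagonal(dist, 0.0)
    vel = np.array([v.velocity for v in instance.vehicles])
    return dist[:, :, None] / vel[None, None, :]


def compute_means(instance: Instance, config: Config = DEFAULT_CONFIG) -> ScalingMeans:
    """Compute the scaling means used by the objective and the index rules.

    mu_h carries an explicit factor 2 (sum of 2*h_ijv over all vehicle/arc
    combinations, divided by |V| |C|^2); it can be disabled via
    ``config.mu_h_factor2``.  mu_gamma averages all |C|^2 road-penalty
    entries, including the (zero) diagonal and unavailable arcs.
    """
    n, nv = instance.n_centers, len(instance.vehicles)
    if n == 0 or nv == 0:
        raise DegenerateInstanceError("compute_means needs >= 1 center and >= 1 vehicle")
    h = transit_time_matrix(instance)
    factor = 2.0 if config.mu_h_factor2 else 1.0
    mu_h = factor * float(h.sum()) / (nv * n * n)
    mu_beta = float(np.mean([v.penalty for v in instance.vehicles]))
    mu_gamma = float(instance.roads.penalty.sum()) / (n * n)
    mu_cr = float(np.mean([v.cold_capacity for v in instance.vehicles]))
    mu_cd = float(np.mean([v.dry_capacity for v in instance.vehicles]))
    mu_v = float(np.mean([v.velocity for v in instance.vehicles]))
    return ScalingMeans(mu_h, mu_gamma, mu_beta, mu_cr, mu_cd, mu_v)


def validate_instance(instance: Instance) -> list[Finding]:
    """Structural and semantic checks.  Returns findings; never raises.

    Structural defects (missing depot, dimension mismatches, nonpositive
    velocities) are errors; capacity overruns at centers are warnings and
    do not block solving.
    """
    findings: list[Finding] = []
    err = lambda m: findings.append(Finding("error", m))
    warn = lambda m: findings.append(Finding("warning", m))

    n, np_, nv = instance.n_centers, len(instance.products), len(instance.vehicles)
    if n < 2:
        err(f"instance needs at least 2 centers, found {n}")
    if nv == 0:
        err("instance has no vehicles")
    if np_ == 0:
        err("instance has no products")

    depots = [c.name for c in instance.centers if c.is_depot]
    if len(depots) != 1:
        err(f"exactly one depot required, found {len(depots)}: {depots}")
    if instance.parameters.start_location and depots:
        if instance.parameters.start_location not in instance.center_names:
            err(
                f"start_location {instance.parameters.start_location!r} "
                "is not a known center"
            )

    if instance.roads.distance.shape != (n, n):
        err(
            f"distance matrix shape {instance.roads.distance.shape} does not "
            f"match {n} centers"
        )
    if instance.demand.shape != (n, np_):
        err(
            f"demand table shape {instance.demand.shape} does not match "
            f"{n} centers x {np_} products"
        )

    for v in instance.vehicles:
        if v.velocity <= 0:
            err(f"vehicle {v.name!r} has nonpositive velocity {v.velocity}")
        if v.penalty <= 0:
            err(f"vehicle {v.name!r} has nonpositive penalty {v.penalty}")
        if v.cold_capacity < 0 or v.dry_capacity < 0:
            err(f"vehicle {v.name!r} has negative capacity")

    if instance.roads.distance.shape == (n, n) and (instance.roads.distance < 0).any():
        err("distance matrix has negative entries")

    p = instance.parameters
    if not 0 <= p.transit_weight_raw <= 10:
        err(f"transit weight {p.transit_weight_raw} outside [0, 10]")
    if p.max_route_hours <= 0:
        err(f"max route time must be positive, got {p.max_route_hours}")
    if p.dropoff_time < 0:
        err(f"drop-off time must be nonnegative, got {p.dropoff_time}")

    if instance.demand.shape == (n, np_):
        if not np.isfinite(instance.demand).all() or (instance.demand < 0).any():
            err("demand table has negative or non-finite entries")
        else:
            if depots and len(depots) == 1:
                o = instance.depot
                if instance.demand[o].sum() > 0:
                    warn(f"depot {depots[0]!r} has nonzero demand; it is never served")
            # storage-capacity overruns are warnings, never blockers
            kcold = np.array(
                [p_.unit_volume if p_.requires_cold else 0.0 for p_ in instance.products]
            )
            kdry = np.array(
                [0.0 if p_.requires_cold else p_.unit_volume for p_ in instance.products]
            )
            for i, c in enumerate(instance.centers):
                if c.is_depot:
                    continue
                vol_c = float(instance.demand[i] @ kcold)
                vol_d = float(instance.demand[i] @ kdry)
                if vol_c > c.cold_capacity:
                    warn(
                        f"center {c.name!r}: cold demand volume {vol_c:.3f} L exceeds "
                        f"cold storage capacity {c.cold_capacity:.3f} L"
                    )
                if vol_d > c.dry_capacity:
                    warn(
                        f"center {c.name!r}: dry demand volume {vol_d:.3f} L exceeds "
                        f"dry storage capacity {c.dry_capacity:.3f} L"
                    )

    return findings


def errors_of(findings: Iterable[Finding]) -> list[Finding]:
    return [f for f in findings if f.severity == "error"]
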