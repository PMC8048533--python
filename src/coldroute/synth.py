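"""Seeded generation of district-like instances and a small worked fixture.

The generator emulates the structure of real district inputs: 8-50 health
centers (one depot), 1-6 vehicles with separate cold/dry capacities and
reliability classes, around a dozen products split between refrigerated and
dry, asymmetric km distances (Euclidean base plus directional jitter, as
with one-way roads or detours), categorical road conditions, and integer
per-center per-product monthly demand.  Everything is reproducible: the
same spec always yields the identical instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    Config,
    DEFAULT_CONFIG,
    ROAD_CONDITION_LABELS,
    VEHICLE_CONDITION_LABELS,
)
from .instance import Center, Instance, Parameters, Product, RoadNetwork, Vehicle

#: Default draw weights over road-condition labels (order as in the
#: vocabulary; "not accessible" kept rare so instances stay connected).
DEFAULT_ROAD_DISTRIBUTION: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15, 0.0, 0.05, 0.05)

DEFAULT_VEHICLE_DISTRIBUTION: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic district.

    ``capacity_tightness`` sets total fleet capacity (per storage class) as a
    multiple of total demand volume: values well above 1 let one route per
    vehicle suffice; values near or below 1 force vehicles onto multiple
    routes.  ``asymmetry_jitter`` is the relative spread of the directional
    distance noise.
    """

    n_centers: int = 11
    n_vehicles: int = 1
    n_products: int = 13
    cold_fraction: float = 0.5
    field_km: float = 80.0
    demand_range: tuple[int, int] = (0, 300)
    capacity_tightness: float = 3.0
    supply_factor: float = 1.3
    road_distribution: tuple[float, ...] = DEFAULT_ROAD_DISTRIBUTION
    vehicle_distribution: tuple[float, ...] = DEFAULT_VEHICLE_DISTRIBUTION
    asymmetry_jitter: float = 0.15
    max_route_hours: float = 8.0
    dropoff_time: float = 0.25
    transit_weight_raw: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_centers < 2:
            raise ValueError(f"need at least 2 centers, got {self.n_centers}")
        if self.n_vehicles < 1:
            raise ValueError(f"need at least 1 vehicle, got {self.n_vehicles}")
        if self.n_products < 1:
            raise ValueError(f"need at least 1 product, got {self.n_products}")
        if not 0 <= self.cold_fraction <= 1:
            raise ValueError("cold_fraction must lie in [0, 1]")
        if len(self.road_distribution) != len(ROAD_CONDITION_LABELS):
            raise ValueError("road_distribution needs one weight per label")


def generate_instance(spec: GeneratorSpec, config: Config = DEFAULT_CONFIG) -> Instance:
    """Draw a full instance from the spec; center 0 is the depot."""
    rng = np.random.default_rng(spec.seed)
    n, nv, npr = spec.n_centers, spec.n_vehicles, spec.n_products

    # --- products: cold ones are small (vaccine vials), dry ones bulkier
    n_cold = int(round(spec.cold_fraction * npr))
    products = []
    for p in range(npr):
        cold = p < n_cold
        products.append(
            Product(
                name=f"P{p:02d}" + ("c" if cold else "d"),
                unit_volume=float(
                    rng.uniform(0.003, 0.02) if cold else rng.uniform(0.01, 0.08)
                ),
                doses_per_vial=int(rng.choice([1, 5, 10, 20])),
                requires_cold=cold,
                available_supply=np.inf,  # set after demand is drawn
            )
        )

    # --- geometry and roads
    coords = rng.uniform(0.0, spec.field_km, size=(n, 2))
    base = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    jitter = 1.0 + spec.asymmetry_jitter * rng.uniform(0.0, 1.0, size=(n, n))
    distance = np.round(base * jitter, 1)
    np.fill_diagonal(distance, 0.0)

    weights = np.asarray(spec.road_distribution, dtype=float)
    weights = weights / weights.sum()
    condition = np.empty((n, n), dtype=object)
    labels = list(ROAD_CONDITION_LABELS)
    for i in range(n):
        condition[i, i] = "fully paved"
        for j in range(i + 1, n):
            lab = labels[int(rng.choice(len(labels), p=weights))]
            if lab == "not accessible" and (i == 0 or j == 0):
                lab = "dirt road (rough quality)"  # keep every center reachable
            condition[i, j] = condition[j, i] = lab
    roads = RoadNetwork.from_labels(distance, condition, config)

    # --- demand: integer doses/units, sparse-ish, none at the depot
    demand = rng.integers(spec.demand_range[0], spec.demand_range[1] + 1, size=(n, npr))
    demand = demand * (rng.uniform(size=(n, npr)) > 0.2)
    demand = demand.astype(float)
    demand[0, :] = 0.0
    products = [
        Product(
            name=p.name,
            unit_volume=p.unit_volume,
            doses_per_vial=p.doses_per_vial,
            requires_cold=p.requires_cold,
            available_supply=float(np.ceil(demand[:, k].sum() * spec.supply_factor)),
        )
        for k, p in enumerate(products)
    ]

    kcold = np.array([p.unit_volume if p.requires_cold else 0.0 for p in products])
    kdry = np.array([0.0 if p.requires_cold else p.unit_volume for p in products])
    vol_cold = demand @ kcold
    vol_dry = demand @ kdry

    # --- centers: storage sized above demand so clean instances warn nothing
    centers = [
        Center(
            name="Depot" if i == 0 else f"C{i:02d}",
            center_type="district store" if i == 0 else "health center",
            cold_capacity=float(
                np.ceil(max(vol_cold[i], 1.0) * rng.uniform(1.3, 2.5))
                if i
                else np.ceil(vol_cold.sum() * 2 + 10)
            ),
            dry_capacity=float(
                np.ceil(max(vol_dry[i], 1.0) * rng.uniform(1.3, 2.5))
                if i
                else np.ceil(vol_dry.sum() * 2 + 10)
            ),
            is_depot=(i == 0),
        )
        for i in range(n)
    ]

    # --- vehicles: fleet capacity = tightness x total demand volume, but
    # --- every vehicle can always carry the single largest center
    vweights = np.asarray(spec.vehicle_distribution, dtype=float)
    vweights = vweights / vweights.sum()
    cold_target = vol_cold.sum() * spec.capacity_tightness / nv
    dry_target = vol_dry.sum() * spec.capacity_tightness / nv
    vehicles = []
    for v in range(nv):
        lab = VEHICLE_CONDITION_LABELS[int(rng.choice(4, p=vweights))]
        share = rng.uniform(0.8, 1.2)
        vehicles.append(
            Vehicle(
                name=f"V{v}",
                condition_class=lab,
                penalty=config.vehicle_penalties[lab],
                velocity=float(np.round(rng.uniform(40.0, 80.0), 1)),
                cold_capacity=float(
                    np.ceil(max(cold_target * share, 1.05 * vol_cold.max(), 1.0))
                ),
                dry_capacity=float(
                    np.ceil(max(dry_target * share, 1.05 * vol_dry.max(), 1.0))
                ),
                fuel_consumption=float(np.round(rng.uniform(0.08, 0.2), 3)),
                fuel_price=1.5,
                per_diem=float(np.round(rng.uniform(20.0, 60.0), 2)),
            )
        )

    params = Parameters(
        run_description=f"synthetic district (seed={spec.seed})",
        start_location=centers[0].name,
        start_time="08:00",
        max_route_hours=spec.max_route_hours,
        dropoff_time=spec.dropoff_time,
        transit_weight_raw=spec.transit_weight_raw,
    )
    return Instance(
        centers=centers,
        products=products,
        vehicles=vehicles,
        roads=roads,
        demand=demand,
        parameters=params,
    )


def oracle_suite_spec(seed: int, n_centers: int, n_vehicles: int) -> GeneratorSpec:
    """Small, guaranteed-solvable shapes used for exhaustive cross-checks:
    compact geography, generous time limit and fleet capacity, fully
    connected road network."""
    return GeneratorSpec(
        n_centers=n_centers,
        n_vehicles=n_vehicles,
        n_products=4,
        cold_fraction=0.5,
        field_km=50.0,
        demand_range=(0, 150),
        capacity_tightness=4.0,
        road_distribution=(0.35, 0.3, 0.2, 0.15, 0.0, 0.0, 0.0),
        max_route_hours=10.0,
        seed=seed,
    )


def fixture_four_centers() -> Instance:
    """A documented four-center, one-vehicle walkthrough fixture.

    One depot ``o`` and three centers ``a``, ``b``, ``c``; the single
    vehicle has penalty 1 ("very reliable") and velocity 60 km/h, so
    transit hours equal distance/60.  Distances and road conditions are
    hand-chosen (synthetic) so that all node-index values along the greedy
    walk are distinct: the construction path is unambiguous.
    """
    dist = np.array(
        [
            [0.0, 60.0, 30.0, 90.0],
            [60.0, 0.0, 45.0, 75.0],
            [30.0, 45.0, 0.0, 60.0],
            [90.0, 75.0, 60.0, 0.0],
        ]
    )
    cond = np.array(
        [
            ["fully paved", "partially paved", "fully paved", "dirt road (rough quality)"],
            ["partially paved", "fully paved", "fully paved", "partially paved"],
            ["fully paved", "fully paved", "fully paved", "dirt road (good quality)"],
            ["dirt road (rough quality)", "partially paved", "dirt road (good quality)", "fully paved"],
        ],
        dtype=object,
    )
    roads = RoadNetwork.from_labels(dist, cond)
    centers = [
        Center(name="o", center_type="district store", cold_capacity=50.0,
               dry_capacity=50.0, is_depot=True),
        Center(name="a", cold_capacity=10.0, dry_capacity=10.0),
        Center(name="b", cold_capacity=10.0, dry_capacity=10.0),
        Center(name="c", cold_capacity=10.0, dry_capacity=10.0),
    ]
    products = [
        Product(name="vaccine", unit_volume=0.01, doses_per_vial=10,
                requires_cold=True, available_supply=1000.0),
        Product(name="syringes", unit_volume=0.05, doses_per_vial=1,
                requires_cold=False, available_supply=1000.0),
    ]
    vehicles = [
        Vehicle(name="truck", condition_class="very reliable", penalty=1.0,
                velocity=60.0, cold_capacity=20.0, dry_capacity=20.0,
                fuel_consumption=0.1, fuel_price=1.5, per_diem=40.0),
    ]
    demand = np.array(
        [
            [0.0, 0.0],
            [200.0, 0.0],
            [150.0, 100.0],
            [0.0, 100.0],
        ]
    )
    params = Parameters(
        run_description="four-center walkthrough fixture",
        start_location="o",
        start_time="08:00",
        max_route_hours=8.0,
        dropoff_time=0.25,
        transit_weight_raw=5.0,
    )
    return Instance(
        centers=centers, products=products, vehicles=vehicles,
        roads=roads, demand=demand, parameters=params,
    )
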