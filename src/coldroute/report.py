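"""Post-hoc reporting: costs, per-product disaggregation, output tables.

Costs are intentionally not part of either objective; they are computed
after routing from per-vehicle fuel consumption, fuel price and personnel
per-diem (one per-diem per executed route, since a route fits inside one
working day).  Grouped cold/dry deliveries are disaggregated back to
per-product dose/unit quantities for the products output sheet.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instance import Instance, Vehicle
from .objective import Route, Solution
from .preprocess import GroupedInstance


class ReconciliationError(RuntimeError):
    """Disaggregated volumes do not reconcile with grouped deliveries."""


def route_costs(route: Route, vehicle: Vehicle, distance: np.ndarray) -> tuple[float, float]:
    """(fuel cost, per-diem cost) of one closed route."""
    if route.stops[0] != route.stops[-1]:
        raise ValueError("route is not closed (does not end at its start)")
    km = float(sum(distance[i, j] for i, j in route.arcs))
    fuel = km * vehicle.fuel_consumption * vehicle.fuel_price
    return fuel, vehicle.per_diem


def route_distance(route: Route, distance: np.ndarray) -> float:
    return float(sum(distance[i, j] for i, j in route.arcs))


def departure_clock_times(route: Route, start_time: str) -> list[str]:
    """Clock time (HH:MM) the vehicle leaves each stop on the route."""
    h, m = (int(x) for x in start_time.split(":"))
    base = h * 60 + m
    out = []
    for dep in route.departures:
        minutes = int(round(base + dep * 60))
        out.append(f"{(minutes // 60) % 24:02d}:{minutes % 60:02d}")
    return out


def disaggregate_products(
    solution: Solution, grouped: GroupedInstance
) -> list[tuple[int, int, int, float]]:
    """Assign per-product quantities to routes.

    Returns (route_index, center, product, quantity_units) records.  A center
    served by a single route receives its full scaled demand there; a center
    split across routes (possible in MIP solutions) is filled product by
    product, in product order, into the routes' delivered volumes of the
    matching storage class.  Totals must reconcile with the grouped volumes
    to within 1e-6 L.
    """
    inst = grouped.instance
    records: list[tuple[int, int, int, float]] = []
    centers_served: dict[int, list[int]] = {}
    for ri, r in enumerate(solution.routes):
        for j in r.deliveries:
            centers_served.setdefault(j, []).append(ri)

    for j, route_ids in sorted(centers_served.items()):
        for is_cold, cls in ((True, 0), (False, 1)):
            shares = [
                (ri, solution.routes[ri].deliveries[j][cls]) for ri in route_ids
            ]
            shares = [(ri, vol) for ri, vol in shares if vol > 0]
            prods = [
                (p, float(grouped.scaled_demand[j, p]))
                for p, prod in enumerate(inst.products)
                if prod.requires_cold == is_cold and grouped.scaled_demand[j, p] > 0
            ]
            si = 0
            remaining_route = shares[si][1] if shares else 0.0
            for p, units in prods:
                k = inst.products[p].unit_volume
                vol_left = units * k
                while vol_left > 1e-12:
                    if si >= len(shares):
                        raise ReconciliationError(
                            f"center {inst.centers[j].name!r}: {vol_left:.6f} L of "
                            f"product {inst.products[p].name!r} has no carrying route"
                        )
                    take = min(vol_left, remaining_route)
                    if take > 0:
                        records.append((shares[si][0], j, p, take / k))
                        vol_left -= take
                        remaining_route -= take
                    if remaining_route <= 1e-12:
                        si += 1
                        remaining_route = shares[si][1] if si < len(shares) else 0.0
            leftover = remaining_route + sum(vol for _, vol in shares[si + 1 :])
            if leftover > 1e-6:
                raise ReconciliationError(
                    f"center {inst.centers[j].name!r}: {leftover:.6f} L of "
                    f"{'cold' if is_cold else 'dry'} delivery has no matching product"
                )
    return records


@dataclass
class RouteReport:
    route: int
    vehicle: str
    condition: str
    total_distance_km: float
    duration_hours: float
    fuel_cost: float
    per_diem_cost: float
    cold_utilization: float
    dry_utilization: float


def summarize_routes(solution: Solution, grouped: GroupedInstance) -> list[RouteReport]:
    inst = grouped.instance
    dist = inst.roads.distance
    out = []
    for ri, r in enumerate(solution.routes):
        veh = inst.vehicles[r.vehicle]
        fuel, diem = route_costs(r, veh, dist)
        out.append(
            RouteReport(
                route=ri,
                vehicle=veh.name,
                condition=veh.condition_class,
                total_distance_km=route_distance(r, dist),
                duration_hours=r.arrival - r.departures[0],
                fuel_cost=fuel,
                per_diem_cost=diem,
                cold_utilization=(r.cold_load() / veh.cold_capacity) if veh.cold_capacity else 0.0,
                dry_utilization=(r.dry_load() / veh.dry_capacity) if veh.dry_capacity else 0.0,
            )
        )
    return out


def routes_table(solution: Solution, grouped: GroupedInstance) -> pd.DataFrame:
    """The routes output sheet: summary rows then per-leg detail rows."""
    inst = grouped.instance
    names = inst.center_names
    rows = []
    for rep, route in zip(summarize_routes(solution, grouped), solution.routes):
        rows.append(
            {
                "record": "summary",
                "route": rep.route,
                "vehicle": rep.vehicle,
                "vehicle_condition": rep.condition,
                "from_center": names[route.stops[0]],
                "to_center": names[route.stops[-1]],
                "road_condition": "",
                "departure": departure_clock_times(route, inst.parameters.start_time)[0],
                "distance_km": round(rep.total_distance_km, 3),
                "duration_hours": round(rep.duration_hours, 3),
                "fuel_cost": round(rep.fuel_cost, 2),
                "per_diem_cost": round(rep.per_diem_cost, 2),
                "cold_utilization": round(rep.cold_utilization, 4),
                "dry_utilization": round(rep.dry_utilization, 4),
                "run_description": inst.parameters.run_description,
            }
        )
    for rep, route in zip(summarize_routes(solution, grouped), solution.routes):
        clocks = departure_clock_times(route, inst.parameters.start_time)
        for k, (i, j) in enumerate(route.arcs):
            rows.append(
                {
                    "record": "leg",
                    "route": rep.route,
                    "vehicle": rep.vehicle,
                    "vehicle_condition": rep.condition,
                    "from_center": names[i],
                    "to_center": names[j],
                    "road_condition": str(inst.roads.condition[i, j]),
                    "departure": clocks[k],
                    "distance_km": round(float(inst.roads.distance[i, j]), 3),
                    "duration_hours": round(float(grouped.transit[i, j, route.vehicle]), 3),
                    "fuel_cost": "",
                    "per_diem_cost": "",
                    "cold_utilization": "",
                    "dry_utilization": "",
                    "run_description": "",
                }
            )
    columns = [
        "record", "route", "vehicle", "vehicle_condition", "from_center", "to_center",
        "road_condition", "departure", "distance_km", "duration_hours", "fuel_cost",
        "per_diem_cost", "cold_utilization", "dry_utilization", "run_description",
    ]
    return pd.DataFrame(rows, columns=columns)


def products_table(solution: Solution, grouped: GroupedInstance) -> pd.DataFrame:
    """The products output sheet: per-route, per-center delivered quantities
    (doses/units) plus utilized center storage capacity."""
    inst = grouped.instance
    records = disaggregate_products(solution, grouped)
    rows = []
    for ri, j, p, qty in records:
        center = inst.centers[j]
        prod = inst.products[p]
        vol = qty * prod.unit_volume
        cold_cap = center.cold_capacity
        dry_cap = center.dry_capacity
        rows.append(
            {
                "route": ri,
                "center": center.name,
                "product": prod.name,
                "storage": "cold" if prod.requires_cold else "dry",
                "quantity": round(qty, 6),
                "volume_liters": round(vol, 6),
                "center_cold_utilization": (
                    round(float(grouped.cold_volume[j]) / cold_cap, 4) if cold_cap else ""
                ),
                "center_dry_utilization": (
                    round(float(grouped.dry_volume[j]) / dry_cap, 4) if dry_cap else ""
                ),
            }
        )
    columns = [
        "route", "center", "product", "storage", "quantity", "volume_liters",
        "center_cold_utilization", "center_dry_utilization",
    ]
    return pd.DataFrame(rows, columns=columns)
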