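"""Read/write the seven-table instance workbook and the two-table result.

Two physical formats are supported everywhere: a real spreadsheet workbook
(``.xlsx``, one sheet per table) and a directory of CSV files (one file per
table, same names).  The CSV form is canonical for tests and version
control; the workbook form is what field users exchange.

Input tables: ``parameters``, ``products``, ``center_capacities``,
``demand``, ``vehicle``, ``distance_data``, ``road_condition``.
Center, product and vehicle names are each entered once (on
``center_capacities``, ``products`` and ``vehicle`` respectively) and must
be consistent across the dependent tables.

Output tables: ``routes`` (per-route summary plus per-leg detail) and
``products`` (per-route, per-center delivered quantities).  The result
filename is the input stem plus ``_result_YYYY-MM-DD`` (numeric suffix on
collision).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    Config,
    DEFAULT_CONFIG,
    ROAD_CONDITION_LABELS,
    VEHICLE_CONDITION_LABELS,
)
from .instance import (
    Center,
    Instance,
    Parameters,
    Product,
    RoadNetwork,
    Vehicle,
)
from .objective import Solution

INPUT_SHEETS = (
    "parameters",
    "products",
    "center_capacities",
    "demand",
    "vehicle",
    "distance_data",
    "road_condition",
)

PARAMETER_KEYS = (
    "run_description",
    "start_location",
    "start_time",
    "max_route_hours",
    "dropoff_time_hours",
    "transit_time_weight",
)


class SchemaError(ValueError):
    """Missing sheet/column or dimension mismatch; message names the sheet."""


def map_road_condition(
    label: str, config: Config = DEFAULT_CONFIG
) -> tuple[float | None, bool]:
    """Label -> (penalty gamma, available flag).

    Penalties increase monotonically from "fully paved" to "foot access
    only"; "not accessible" has no penalty and is simply unavailable.
    """
    if label not in ROAD_CONDITION_LABELS:
        raise ValueError(f"unknown road condition label {label!r}")
    if label == "not accessible":
        return None, False
    return config.road_penalties[label], True


def map_vehicle_condition(label: str, config: Config = DEFAULT_CONFIG) -> float:
    """Label -> vehicle penalty beta (monotone over the 4 ordered labels)."""
    if label not in VEHICLE_CONDITION_LABELS:
        raise ValueError(f"unknown vehicle condition label {label!r}")
    return config.vehicle_penalties[label]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_tables(path: Path) -> dict[str, pd.DataFrame]:
    if path.is_dir():
        tables = {}
        for name in INPUT_SHEETS:
            f = path / f"{name}.csv"
            if not f.exists():
                raise SchemaError(f"missing input table {name!r} ({f})")
            tables[name] = pd.read_csv(f, dtype=str).dropna(how="all")
        return tables
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        book = pd.read_excel(path, sheet_name=None, dtype=str)
        missing = [s for s in INPUT_SHEETS if s not in book]
        if missing:
            raise SchemaError(f"workbook {path} is missing sheet(s): {missing}")
        return {s: book[s].dropna(how="all") for s in INPUT_SHEETS}
    raise SchemaError(f"unsupported input {path}: expected .xlsx or a directory of CSVs")


def _require_columns(df: pd.DataFrame, cols: list[str], sheet: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"sheet {sheet!r} is missing column(s): {missing}")


def _as_float(value, sheet: str, where: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"sheet {sheet!r}: non-numeric value {value!r} at {where}") from None


_BOOL = {"yes": True, "y": True, "true": True, "1": True,
         "no": False, "n": False, "false": False, "0": False}


def _as_bool(value, sheet: str, where: str) -> bool:
    key = str(value).strip().lower()
    if key not in _BOOL:
        raise SchemaError(f"sheet {sheet!r}: expected yes/no at {where}, got {value!r}")
    return _BOOL[key]


def read_instance(path: str | Path, config: Config = DEFAULT_CONFIG) -> Instance:
    """Parse an instance from a workbook or a CSV directory."""
    path = Path(path)
    tables = _read_tables(path)

    # parameters: key/value pairs
    pdf = tables["parameters"]
    _require_columns(pdf, ["key", "value"], "parameters")
    kv = dict(zip(pdf["key"].astype(str).str.strip(), pdf["value"]))
    missing = [k for k in PARAMETER_KEYS if k not in kv]
    if missing:
        raise SchemaError(f"sheet 'parameters' is missing key(s): {missing}")
    params = Parameters(
        run_description=str(kv["run_description"]) if pd.notna(kv["run_description"]) else "",
        start_location=str(kv["start_location"]).strip(),
        start_time=str(kv["start_time"]).strip(),
        max_route_hours=_as_float(kv["max_route_hours"], "parameters", "max_route_hours"),
        dropoff_time=_as_float(kv["dropoff_time_hours"], "parameters", "dropoff_time_hours"),
        transit_weight_raw=_as_float(
            kv["transit_time_weight"], "parameters", "transit_time_weight"
        ),
    )

    # products
    prdf = tables["products"]
    _require_columns(
        prdf,
        ["product", "unit_volume_liters", "doses_per_vial", "requires_cold", "available_supply"],
        "products",
    )
    products = []
    for _, row in prdf.iterrows():
        supply_raw = str(row["available_supply"]).strip().lower()
        supply = float("inf") if supply_raw in ("", "inf", "nan") else _as_float(
            row["available_supply"], "products", f"available_supply of {row['product']!r}"
        )
        products.append(
            Product(
                name=str(row["product"]).strip(),
                unit_volume=_as_float(
                    row["unit_volume_liters"], "products", f"unit_volume of {row['product']!r}"
                ),
                doses_per_vial=int(
                    _as_float(row["doses_per_vial"], "products", f"doses_per_vial of {row['product']!r}")
                ),
                requires_cold=_as_bool(
                    row["requires_cold"], "products", f"requires_cold of {row['product']!r}"
                ),
                available_supply=supply,
            )
        )

    # centers
    cdf = tables["center_capacities"]
    _require_columns(
        cdf, ["center", "center_type", "cold_capacity_liters", "dry_capacity_liters"],
        "center_capacities",
    )
    center_names = [str(x).strip() for x in cdf["center"]]
    if params.start_location not in center_names:
        raise SchemaError(
            f"parameters.start_location {params.start_location!r} is not a center "
            f"on 'center_capacities'"
        )
    centers = [
        Center(
            name=name,
            center_type=str(row["center_type"]),
            cold_capacity=_as_float(
                row["cold_capacity_liters"], "center_capacities", f"cold capacity of {name!r}"
            ),
            dry_capacity=_as_float(
                row["dry_capacity_liters"], "center_capacities", f"dry capacity of {name!r}"
            ),
            is_depot=(name == params.start_location),
        )
        for name, (_, row) in zip(center_names, cdf.iterrows())
    ]

    # vehicles
    vdf = tables["vehicle"]
    _require_columns(
        vdf,
        ["vehicle", "condition", "velocity_kmh", "cold_capacity_liters",
         "dry_capacity_liters", "fuel_consumption_l_per_km", "fuel_price_per_liter",
         "per_diem"],
        "vehicle",
    )
    vehicles = []
    for _, row in vdf.iterrows():
        name = str(row["vehicle"]).strip()
        label = str(row["condition"]).strip()
        vehicles.append(
            Vehicle(
                name=name,
                condition_class=label,
                penalty=map_vehicle_condition(label, config),
                velocity=_as_float(row["velocity_kmh"], "vehicle", f"velocity of {name!r}"),
                cold_capacity=_as_float(
                    row["cold_capacity_liters"], "vehicle", f"cold capacity of {name!r}"
                ),
                dry_capacity=_as_float(
                    row["dry_capacity_liters"], "vehicle", f"dry capacity of {name!r}"
                ),
                fuel_consumption=_as_float(
                    row["fuel_consumption_l_per_km"], "vehicle", f"fuel consumption of {name!r}"
                ),
                fuel_price=_as_float(
                    row["fuel_price_per_liter"], "vehicle", f"fuel price of {name!r}"
                ),
                per_diem=_as_float(row["per_diem"], "vehicle", f"per diem of {name!r}"),
            )
        )

    # matrices: demand (centers x products), distance, road condition
    def matrix_frame(name: str, columns: list[str]) -> pd.DataFrame:
        df = tables[name]
        first = df.columns[0]
        df = df.set_index(first)
        df.index = [str(x).strip() for x in df.index]
        got = [str(c).strip() for c in df.columns]
        if list(df.index) != center_names:
            raise SchemaError(
                f"sheet {name!r}: row centers {list(df.index)} do not match "
                f"'center_capacities' ({center_names})"
            )
        if got != columns:
            raise SchemaError(
                f"sheet {name!r}: columns {got} do not match expected {columns}"
            )
        return df

    product_names = [p.name for p in products]
    ddf = matrix_frame("demand", product_names)
    demand = np.array(
        [
            [_as_float(ddf.iloc[i, j], "demand", f"({center_names[i]}, {product_names[j]})")
             for j in range(len(product_names))]
            for i in range(len(center_names))
        ]
    )

    xdf = matrix_frame("distance_data", center_names)
    n = len(center_names)
    distance = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            cell = xdf.iloc[i, j]
            if pd.isna(cell) or str(cell).strip() == "":
                raise SchemaError(
                    f"sheet 'distance_data': blank distance at "
                    f"({center_names[i]}, {center_names[j]}); use road condition "
                    f"'not accessible' for unusable roads"
                )
            distance[i, j] = _as_float(cell, "distance_data", f"({center_names[i]}, {center_names[j]})")

    rdf = matrix_frame("road_condition", center_names)
    condition = np.empty((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            label = str(rdf.iloc[i, j]).strip()
            if label not in ROAD_CONDITION_LABELS:
                raise ValueError(
                    f"sheet 'road_condition': unknown label {label!r} at "
                    f"({center_names[i]}, {center_names[j]})"
                )
            condition[i, j] = label

    roads = RoadNetwork.from_labels(distance, condition, config)
    return Instance(
        centers=centers,
        products=products,
        vehicles=vehicles,
        roads=roads,
        demand=demand,
        parameters=params,
    )


# ---------------------------------------------------------------------------
# Writing instances (round-trip support, used by the generator)
# ---------------------------------------------------------------------------

def instance_tables(instance: Instance) -> dict[str, pd.DataFrame]:
    """The seven input tables of an instance as DataFrames."""
    p = instance.parameters
    params = pd.DataFrame(
        {
            "key": list(PARAMETER_KEYS),
            "value": [
                p.run_description,
                p.start_location,
                p.start_time,
                p.max_route_hours,
                p.dropoff_time,
                p.transit_weight_raw,
            ],
        }
    )
    products = pd.DataFrame(
        {
            "product": [x.name for x in instance.products],
            "unit_volume_liters": [x.unit_volume for x in instance.products],
            "doses_per_vial": [x.doses_per_vial for x in instance.products],
            "requires_cold": ["yes" if x.requires_cold else "no" for x in instance.products],
            "available_supply": [
                "inf" if np.isinf(x.available_supply) else x.available_supply
                for x in instance.products
            ],
        }
    )
    centers = pd.DataFrame(
        {
            "center": instance.center_names,
            "center_type": [c.center_type for c in instance.centers],
            "cold_capacity_liters": [c.cold_capacity for c in instance.centers],
            "dry_capacity_liters": [c.dry_capacity for c in instance.centers],
        }
    )
    vehicles = pd.DataFrame(
        {
            "vehicle": instance.vehicle_names,
            "condition": [v.condition_class for v in instance.vehicles],
            "velocity_kmh": [v.velocity for v in instance.vehicles],
            "cold_capacity_liters": [v.cold_capacity for v in instance.vehicles],
            "dry_capacity_liters": [v.dry_capacity for v in instance.vehicles],
            "fuel_consumption_l_per_km": [v.fuel_consumption for v in instance.vehicles],
            "fuel_price_per_liter": [v.fuel_price for v in instance.vehicles],
            "per_diem": [v.per_diem for v in instance.vehicles],
        }
    )
    demand = pd.DataFrame(
        instance.demand, index=instance.center_names, columns=instance.product_names
    ).rename_axis("center").reset_index()
    distance = pd.DataFrame(
        instance.roads.distance, index=instance.center_names, columns=instance.center_names
    ).rename_axis("from_center").reset_index()
    condition = pd.DataFrame(
        instance.roads.condition, index=instance.center_names, columns=instance.center_names
    ).rename_axis("from_center").reset_index()
    return {
        "parameters": params,
        "products": products,
        "center_capacities": centers,
        "demand": demand,
        "vehicle": vehicles,
        "distance_data": distance,
        "road_condition": condition,
    }


def write_instance(instance: Instance, path: str | Path) -> Path:
    """Write the seven tables as a CSV directory or an .xlsx workbook."""
    path = Path(path)
    tables = instance_tables(instance)
    if path.suffix.lower() == ".xlsx":
        path.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            for name, df in tables.items():
                df.to_excel(xl, sheet_name=name, index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(path / f"{name}.csv", index=False)
    return path


# ---------------------------------------------------------------------------
# Writing solutions
# ---------------------------------------------------------------------------

def result_path(input_path: str | Path, date: _dt.date | None = None) -> Path:
    """Output location: input stem + "_result_" + ISO date, numeric suffix on
    collision.  Directory inputs produce a sibling directory; workbook inputs
    produce a workbook."""
    input_path = Path(input_path)
    date = date or _dt.date.today()
    stem = input_path.stem if input_path.suffix else input_path.name
    suffix = input_path.suffix if input_path.suffix.lower() == ".xlsx" else ""
    base = input_path.parent / f"{stem}_result_{date.isoformat()}"
    candidate = base.with_suffix(suffix) if suffix else base
    k = 1
    while candidate.exists():
        candidate = (
            base.parent / f"{base.name}_{k}{suffix}"
            if suffix
            else base.parent / f"{base.name}_{k}"
        )
        k += 1
    return candidate


def write_solution(
    solution: Solution,
    instance: Instance,
    path: str | Path,
    grouped=None,
) -> Path:
    """Write the routes + products result tables next to ``path``.

    ``path`` is the target output file (.xlsx) or directory (CSV pair).
    """
    from .preprocess import group_products
    from .report import routes_table, products_table

    if grouped is None:
        grouped = group_products(instance)
    path = Path(path)
    routes_df = routes_table(solution, grouped)
    products_df = products_table(solution, grouped)
    if path.suffix.lower() == ".xlsx":
        path.parent.mkdir(parents=True, exist_ok=True)
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            routes_df.to_excel(xl, sheet_name="routes", index=False)
            products_df.to_excel(xl, sheet_name="products", index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        routes_df.to_csv(path / "routes.csv", index=False)
        products_df.to_csv(path / "products.csv", index=False)
    return path
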