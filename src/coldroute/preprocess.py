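"""Preprocessing: weight normalization, demand scaling, cold/dry grouping.

The optimization operates on only two product classes — refrigerated (cold)
and nonrefrigerated (dry) — obtained by summing per-product demand volumes.
This keeps the number of flow variables independent of the product count;
per-product detail is retained for post-hoc disaggregation in the report
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .instance import (
    Finding,
    Instance,
    ScalingMeans,
    compute_means,
    transit_time_matrix,
)


def normalize_weights(raw: float) -> tuple[float, float]:
    """Map the user's 0-10 transit-time weight to (W_t, W_p), W_t + W_p = 1.

    10 means pure transit-time minimization, 0 pure penalty (risk)
    minimization.
    """
    if not 0 <= raw <= 10:
        raise ValueError(f"transit weight must lie in [0, 10], got {raw}")
    wt = raw / 10.0
    return wt, 1.0 - wt


def scale_demand(demand: np.ndarray, supplies: np.ndarray) -> np.ndarray:
    """Scale each product's demand column down to the available supply.

    Columns whose total demand exceeds the supply are scaled proportionally
    and rounded to whole units by the largest-remainder rule (ties broken by
    center order), so the scaled column sum never exceeds the supply.
    Columns already within supply are returned unchanged.
    """
    demand = np.asarray(demand, dtype=float)
    scaled = demand.copy()
    for p in range(demand.shape[1]):
        total = demand[:, p].sum()
        supply = supplies[p]
        if not np.isfinite(supply) or total <= supply or total == 0:
            continue
        exact = demand[:, p] * (supply / total)
        floors = np.floor(exact)
        leftover = int(np.floor(min(supply, exact.sum()) - floors.sum() + 1e-9))
        remainders = exact - floors
        # largest remainder first; ties by center order (stable sort on -r)
        order = np.argsort(-remainders, kind="stable")
        add = np.zeros_like(floors)
        add[order[:leftover]] = 1.0
        scaled[:, p] = floors + add
    return scaled


@dataclass
class GroupedInstance:
    """Preprocessed instance: the direct input to both solvers.

    cold/dry demand volumes are liters per center; ``scaled_demand`` keeps
    the per-product unit detail for disaggregation.
    """

    instance: Instance
    scaled_demand: np.ndarray  # units, (n_centers, n_products)
    cold_volume: np.ndarray  # D_i^r, liters, (n_centers,)
    dry_volume: np.ndarray  # D_i^d, liters, (n_centers,)
    means: ScalingMeans
    w_transit: float  # W_t
    w_penalty: float  # W_p
    transit: np.ndarray  # h_ijv, (n, n, |V|)
    config: Config = DEFAULT_CONFIG

    @property
    def depot(self) -> int:
        return self.instance.depot

    @property
    def n_centers(self) -> int:
        return self.instance.n_centers

    @property
    def n_vehicles(self) -> int:
        return len(self.instance.vehicles)

    def demanded_centers(self) -> list[int]:
        """Centers (excluding the depot) with positive demand volume."""
        o = self.depot
        return [
            i
            for i in range(self.n_centers)
            if i != o and (self.cold_volume[i] > 0 or self.dry_volume[i] > 0)
        ]


def group_products(
    instance: Instance,
    scaled_demand: np.ndarray | None = None,
    config: Config = DEFAULT_CONFIG,
) -> GroupedInstance:
    """Build the two-class (cold/dry) optimization input from an instance.

    Scales demand to supply first unless a pre-scaled table is supplied.
    """
    if scaled_demand is None:
        supplies = np.array([p.available_supply for p in instance.products])
        scaled_demand = scale_demand(instance.demand, supplies)
    kcold = np.array(
        [p.unit_volume if p.requires_cold else 0.0 for p in instance.products]
    )
    kdry = np.array(
        [0.0 if p.requires_cold else p.unit_volume for p in instance.products]
    )
    cold = scaled_demand @ kcold
    dry = scaled_demand @ kdry
    o = instance.depot
    cold[o] = 0.0
    dry[o] = 0.0
    wt, wp = normalize_weights(instance.parameters.transit_weight_raw)
    return GroupedInstance(
        instance=instance,
        scaled_demand=scaled_demand,
        cold_volume=cold,
        dry_volume=dry,
        means=compute_means(instance, config),
        w_transit=wt,
        w_penalty=wp,
        transit=transit_time_matrix(instance),
        config=config,
    )


def storage_warnings(grouped: GroupedInstance) -> list[Finding]:
    """One warning per (center, storage class) whose scaled demand volume
    exceeds that center's storage capacity.  Informational only."""
    out: list[Finding] = []
    inst = grouped.instance
    for i, c in enumerate(inst.centers):
        if c.is_depot:
            continue
        if grouped.cold_volume[i] > c.cold_capacity:
            out.append(
                Finding(
                    "warning",
                    f"center {c.name!r}: cold demand {grouped.cold_volume[i]:.3f} L "
                    f"exceeds cold storage {c.cold_capacity:.3f} L",
                )
            )
        if grouped.dry_volume[i] > c.dry_capacity:
            out.append(
                Finding(
                    "warning",
                    f"center {c.name!r}: dry demand {grouped.dry_volume[i]:.3f} L "
                    f"exceeds dry storage {c.dry_capacity:.3f} L",
                )
            )
    return out
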