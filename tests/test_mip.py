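import math

import numpy as np
import pytest

from conftest import oracle_grouped
from oracle import brute_force_optimum

from coldroute.config import DEFAULT_CONFIG
from coldroute.instance import ScalingMeans
from coldroute.mip import (
    BuildError,
    MIPConfig,
    build_model,
    count_variables,
    extract_routes,
    solve_mip,
)
from coldroute.objective import arc_cost, solution_cost
from coldroute.preprocess import group_products
from coldroute.synth import GeneratorSpec, generate_instance, oracle_suite_spec
from coldroute.verify import audit_solution


class TestArcCost:
    def test_all_at_mean_values(self):
        means = ScalingMeans(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        got = arc_cost(1.0, 1.0, 1.0, 0.5, 0.5, means, "printed")
        assert got == pytest.approx(1.5 * math.exp(-1))  # ~0.5518
        got_inc = arc_cost(1.0, 1.0, 1.0, 0.5, 0.5, means, "increasing")
        assert got_inc == pytest.approx(1.5 * math.e)

    def test_pure_transit_weight_ignores_penalties(self):
        means = ScalingMeans(2.0, 3.0, 4.0, 1.0, 1.0, 1.0)
        assert arc_cost(1.0, 99.0, 99.0, 1.0, 0.0, means) == pytest.approx(
            math.exp(-0.5)
        )

    @pytest.mark.parametrize("form", ["printed", "increasing"])
    def test_matches_direct_formula_and_is_positive(self, form):
        rng = np.random.default_rng(0)
        means = ScalingMeans(1.3, 2.1, 2.5, 40.0, 80.0, 55.0)
        sign = -1 if form == "printed" else 1
        for _ in range(20):
            h, g, b = rng.uniform(0.01, 5, 3)
            wt = rng.uniform()
            expected = wt * math.exp(sign * h / 1.3) + (1 - wt) * (
                math.exp(sign * g / 2.1) + math.exp(sign * b / 2.5)
            )
            got = arc_cost(h, g, b, wt, 1 - wt, means, form)
            assert got == pytest.approx(expected, rel=1e-12)
            assert got > 0


class TestModelShape:
    @pytest.mark.parametrize(
        "n, v, expected",
        [(8, 1, 200), (8, 2, 400), (8, 3, 600), (11, 1, 374), (16, 2, 1568), (13, 6, 3120)],
    )
    def test_variable_count_matches_published_district_shapes(self, n, v, expected):
        assert count_variables(n, v) == expected
        inst = generate_instance(GeneratorSpec(n_centers=n, n_vehicles=v, seed=1))
        model = build_model(group_products(inst))
        assert model.n_variables == expected

    def test_degenerate_instance_rejected(self, four_centers):
        import dataclasses

        from coldroute.instance import DegenerateInstanceError

        inst = dataclasses.replace(four_centers, vehicles=[])
        with pytest.raises((BuildError, DegenerateInstanceError)):
            build_model(group_products(inst))


class TestSolveMip:
    def test_zero_demand_gives_empty_optimal_plan(self):
        inst = generate_instance(oracle_suite_spec(seed=2, n_centers=4, n_vehicles=1))
        inst.demand[:] = 0.0
        g = group_products(inst)
        sol = solve_mip(build_model(g))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert sol.y.sum() == 0
        assert extract_routes(sol, g).routes == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 5])
    def test_single_vehicle_optimum_equals_enumeration(self, seed):
        g = oracle_grouped(seed * 2)  # even seeds -> 1 vehicle
        sol = solve_mip(build_model(g, MIPConfig.for_instance(g, time_limit=60)))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(brute_force_optimum(g), abs=1e-6)

    def test_unreachable_center_makes_model_infeasible(self):
        inst = generate_instance(oracle_suite_spec(seed=4, n_centers=4, n_vehicles=1))
        j = inst.n_centers - 1
        inst.demand[j, :] = 100.0  # ensure j is demanded
        for i in range(inst.n_centers):
            if i != j:
                inst.roads.condition[i, j] = "not accessible"
                inst.roads.availability[i, j] = 0
        g = group_products(inst)
        sol = solve_mip(build_model(g))
        assert sol.status == "infeasible"
        name = inst.centers[j].name
        assert any(name in d for d in sol.diagnostics)

    def test_bigger_big_m_leaves_optimum_unchanged(self):
        g = oracle_grouped(6)
        base = MIPConfig.for_instance(g, time_limit=60)
        ref = solve_mip(build_model(g, base)).objective
        bigger = MIPConfig.for_instance(
            g,
            time_limit=60,
            m_time=10 * base.m_time,
            m_count=10 * base.m_count,
            m_flow=(10 * base.m_flow[0], 10 * base.m_flow[1]),
        )
        assert solve_mip(build_model(g, bigger)).objective == pytest.approx(ref, abs=1e-6)

    def test_objective_invariant_to_center_relabeling(self):
        """Permuting the non-depot centers leaves the optimum unchanged."""
        inst = generate_instance(oracle_suite_spec(seed=9, n_centers=5, n_vehicles=1))
        g = group_products(inst)
        ref = solve_mip(build_model(g)).objective

        perm = [0, 3, 1, 4, 2]  # depot fixed
        import copy

        inst2 = copy.deepcopy(inst)
        inst2.centers = [inst.centers[p] for p in perm]
        inst2.demand = inst.demand[perm]
        inst2.roads = type(inst.roads)(
            distance=inst.roads.distance[np.ix_(perm, perm)],
            condition=inst.roads.condition[np.ix_(perm, perm)],
            penalty=inst.roads.penalty[np.ix_(perm, perm)],
            availability=inst.roads.availability[np.ix_(perm, perm)],
        )
        got = solve_mip(build_model(group_products(inst2))).objective
        assert got == pytest.approx(ref, abs=1e-6)


class TestExtractRoutes:
    def test_routes_start_and_end_at_depot_with_increasing_times(self):
        g = oracle_grouped(3)  # 2 vehicles
        sol = solve_mip(build_model(g))
        routes = extract_routes(sol, g)
        assert audit_solution(routes, g) == []
        for r in routes.routes:
            assert r.stops[0] == g.depot and r.stops[-1] == g.depot
            assert r.departures == sorted(r.departures)
        # extracted arc set reproduces the MIP objective
        assert solution_cost(routes, g) == pytest.approx(sol.objective, abs=1e-6)

    def test_mip_feasibility_constraints_hold(self):
        """Flow conservation, initial loads, durations and availability of
        the returned y/x/t, checked directly on the arrays."""
        g = oracle_grouped(7)
        sol = solve_mip(build_model(g))
        inst = g.instance
        o = g.depot
        demand = np.stack([g.cold_volume, g.dry_volume], axis=1)
        for p in range(2):
            for j in range(g.n_centers):
                if j == o:
                    continue
                net = sol.x[:, j, :, p].sum() - sol.x[j, :, :, p].sum()
                assert net == pytest.approx(demand[j, p], abs=1e-6)
        caps = [
            [v.cold_capacity for v in inst.vehicles],
            [v.dry_capacity for v in inst.vehicles],
        ]
        for p in range(2):
            for v in range(g.n_vehicles):
                init = sol.x[o, :, v, p].sum() - sol.x[o, o, v, p]
                assert init <= caps[p][v] + 1e-6
        assert (sol.y <= inst.roads.availability[:, :, None] + 1e-9).all()
        assert np.einsum("iiv->iv", sol.y).sum() == 0
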