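import itertools
import math

import numpy as np
import pytest

from conftest import oracle_grouped
from oracle import brute_force_optimum

from coldroute.instance import ScalingMeans
from coldroute.objective import solution_cost
from coldroute.preprocess import group_products
from coldroute.solver import (
    InfeasibleRoutingError,
    RouteState,
    branch_and_bound,
    construct_greedy,
    elite_partition,
    feasible_extension,
    mst_lower_bound,
    node_index,
    vehicle_index,
    vehicle_order,
    _fresh_state,
)
from coldroute.synth import GeneratorSpec, generate_instance, oracle_suite_spec
from coldroute.verify import audit_solution


class TestIndices:
    def test_vehicle_index_all_at_mean(self, four_centers):
        means = ScalingMeans(1.0, 1.0, 1.0, 20.0, 20.0, 60.0)
        got = vehicle_index(four_centers.vehicles[0], means)
        assert got == pytest.approx(math.exp(-1) + 3 * math.e)  # ~8.5227

    def test_vehicle_index_prefers_lower_penalty(self, four_centers):
        import dataclasses

        means = ScalingMeans(1.0, 1.0, 2.0, 20.0, 20.0, 60.0)
        v1 = four_centers.vehicles[0]
        v2 = dataclasses.replace(v1, penalty=4.0)
        assert vehicle_index(v1, means) > vehicle_index(v2, means)

    def test_vehicle_index_matches_formula(self, small_grouped):
        m = small_grouped.means
        for veh in small_grouped.instance.vehicles:
            expected = (
                math.exp(-veh.penalty / m.mu_beta)
                + math.exp(veh.cold_capacity / m.mu_cr)
                + math.exp(veh.dry_capacity / m.mu_cd)
                + math.exp(veh.velocity / m.mu_v)
            )
            assert vehicle_index(veh, m) == pytest.approx(expected, rel=1e-12)

    def test_node_index_matches_formula_and_drives_greedy(self, four_centers_grouped):
        g = four_centers_grouped
        m = g.means
        scores = {}
        for j in (1, 2, 3):
            expected = g.w_transit * math.exp(
                -g.transit[0, j, 0] / m.mu_h
            ) + g.w_penalty * math.exp(-g.instance.roads.penalty[0, j] / m.mu_gamma)
            got = node_index(g, 0, j, 0)
            assert got == pytest.approx(expected, rel=1e-12)
            scores[j] = got
        # fixture designed tie-free: a unique argmax leaves the depot
        ranked = sorted(scores, key=scores.get, reverse=True)
        assert scores[ranked[0]] > scores[ranked[1]]
        sol = construct_greedy(g)
        assert sol.routes[0].stops[1] == ranked[0]

    def test_node_index_limit_with_pure_transit_weight(self, four_centers):
        import dataclasses

        inst = four_centers
        inst2 = dataclasses.replace(
            inst, parameters=dataclasses.replace(inst.parameters, transit_weight_raw=10.0)
        )
        g = group_products(inst2)
        g.transit[0, 1, 0] = 0.0
        assert node_index(g, 0, 1, 0) == pytest.approx(1.0)


class TestFeasibleExtension:
    def test_accepts_with_ample_resources(self, four_centers_grouped):
        state = _fresh_state(four_centers_grouped, 0)
        ok, reason = feasible_extension(state, 2, four_centers_grouped)
        assert ok and reason == "ok"

    def test_rejects_unavailable_road(self, four_centers_grouped):
        g = four_centers_grouped
        g.instance.roads.availability[0, 3] = 0
        try:
            ok, reason = feasible_extension(_fresh_state(g, 0), 3, g)
            assert not ok and "unavailable" in reason
        finally:
            g.instance.roads.availability[0, 3] = 1

    def test_capacity_violation_named(self, four_centers_grouped):
        g = four_centers_grouped
        state = RouteState(
            vehicle=0, stops=(0,), departures=(0.0,), time=0.0, rem_cold=1.0, rem_dry=20.0
        )
        ok, reason = feasible_extension(state, 1, g)  # needs 2 L cold
        assert not ok and reason == "cold capacity exceeded"

    def test_time_boundary_exact_return_accepted_one_minute_more_rejected(
        self, four_centers_grouped
    ):
        g = four_centers_grouped
        v = 0
        # visiting c from the depot: 1.5 h out + 0.25 h drop-off + 1.5 h back
        need = g.transit[0, 3, v] + g.instance.parameters.dropoff_time + g.transit[3, 0, v]
        state = _fresh_state(g, v)
        tight = g.instance.parameters.max_route_hours - need
        assert feasible_extension(
            RouteState(v, (0,), (0.0,), tight, 20.0, 20.0), 3, g
        )[0]
        over = tight + 1.0 / 60.0
        ok, reason = feasible_extension(RouteState(v, (0,), (0.0,), over, 20.0, 20.0), 3, g)
        assert not ok and reason == "route time limit exceeded"


class TestGreedy:
    def test_single_vehicle_visits_all_three_by_index_chain(self, four_centers_grouped):
        g = four_centers_grouped
        sol = construct_greedy(g)
        assert len(sol.routes) == 1
        route = sol.routes[0]
        assert sorted(route.stops[1:-1]) == [1, 2, 3]
        # the sequence is exactly the argmax chain of the node index
        unserved = {1, 2, 3}
        cur = 0
        for stop in route.stops[1:-1]:
            best = max(unserved, key=lambda j: node_index(g, cur, j, 0))
            assert stop == best
            unserved.discard(stop)
            cur = stop
        assert audit_solution(sol, g) == []

    def test_zero_demand_yields_empty_solution(self, four_centers):
        import copy

        inst = copy.deepcopy(four_centers)
        inst.demand[:] = 0.0
        sol = construct_greedy(group_products(inst))
        assert sol.routes == [] and sol.objective == 0.0

    def test_demand_split_uses_both_vehicles_before_reuse(self):
        """Fleet capacity below total demand forces a split; with two
        vehicles both must appear before any second route."""
        inst = generate_instance(
            GeneratorSpec(n_centers=8, n_vehicles=2, capacity_tightness=0.9, seed=21)
        )
        g = group_products(inst)
        sol = construct_greedy(g)
        vehicles_in_order = [r.vehicle for r in sol.routes]
        assert len(sol.routes) >= 2
        assert set(vehicles_in_order[:2]) == {0, 1}
        assert audit_solution(sol, g) == []

    def test_unservable_center_raises_with_name(self):
        inst = generate_instance(oracle_suite_spec(seed=4, n_centers=4, n_vehicles=1))
        j = 2
        inst.demand[j, :] = 50.0
        for i in range(inst.n_centers):
            if i != j:
                inst.roads.availability[i, j] = 0
                inst.roads.condition[i, j] = "not accessible"
        with pytest.raises(InfeasibleRoutingError, match=inst.centers[j].name):
            construct_greedy(group_products(inst))

    def test_greedy_on_fixture_is_optimal_among_all_visit_orders(
        self, four_centers_grouped
    ):
        """One vehicle, three centers: enumerate the 6 orders; the fixture's
        greedy chain lands on a feasible order (not necessarily cheapest,
        greedy maximizes the index), and all orders are feasible here."""
        g = four_centers_grouped
        sol = construct_greedy(g)
        costs = []
        for perm in itertools.permutations([1, 2, 3]):
            stops = [0, *perm, 0]
            from coldroute.objective import Route

            r = Route(vehicle=0, stops=stops, departures=[0.0] * 4, arrival=0.0)
            costs.append(solution_cost([r], g))
        assert min(costs) <= sol.objective <= max(costs)


class TestMSTBound:
    def test_forced_triangle(self, four_centers_grouped):
        """With only three nodes the MST takes the two cheapest edges."""
        g = four_centers_grouped
        from coldroute.objective import arc_cost_matrix
        from coldroute.solver import _undirected_cost

        und = _undirected_cost(g, arc_cost_matrix(g))
        nodes = [0, 1, 2]
        bound, connected = mst_lower_bound(nodes, g)
        pair_costs = sorted(und[i, j] for i, j in [(0, 1), (0, 2), (1, 2)])
        assert connected
        assert bound == pytest.approx(sum(pair_costs[:2]))

    def test_single_unserved_center_bound_is_cheapest_connection(self, four_centers_grouped):
        g = four_centers_grouped
        from coldroute.objective import arc_cost_matrix
        from coldroute.solver import _undirected_cost

        und = _undirected_cost(g, arc_cost_matrix(g))
        bound, _ = mst_lower_bound([0, 3], g)
        assert bound == pytest.approx(und[0, 3])

    @pytest.mark.parametrize("seed", range(8))
    def test_bound_below_enumerated_optimum(self, seed):
        g = oracle_grouped(seed)
        opt = brute_force_optimum(g)
        bound, connected = mst_lower_bound([g.depot] + g.demanded_centers(), g)
        assert connected
        assert bound <= opt + 1e-9

    def test_disconnected_set_flagged(self, four_centers_grouped):
        g = four_centers_grouped
        avail = g.instance.roads.availability
        saved = avail.copy()
        avail[3, :] = 0
        avail[:, 3] = 0
        try:
            bound, connected = mst_lower_bound([0, 1, 3], g)
            assert not connected
            assert bound >= 0
        finally:
            avail[:] = saved


class TestElitePartition:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (0, (0, 0)),
            (1, (1, 0)),
            (2, (1, 1)),  # min one slot per half once there are 2+ branches
            (10, (1, 1)),  # ceil(1.2) = 2 -> 1 best + 1 uncertainty
            (20, (2, 1)),  # ceil(2.4) = 3
            (50, (3, 3)),
        ],
    )
    def test_twelve_percent_half_and_half(self, n, expected):
        assert elite_partition(n) == expected


class TestBranchAndBound:
    @pytest.mark.parametrize("form", ["printed", "increasing"])
    @pytest.mark.parametrize("seed", [0, 1, 3, 8])
    def test_uncapped_search_reaches_enumerated_optimum(self, seed, form):
        g = oracle_grouped(seed, form)
        sol = branch_and_bound(g, budget_s=300)
        assert sol.objective == pytest.approx(brute_force_optimum(g), abs=1e-6)
        assert sol.gap == pytest.approx(0.0, abs=1e-9)
        assert sol.status == "optimal"
        assert audit_solution(sol, g) == []

    def test_tiny_budget_falls_back_to_greedy(self, medium_grouped):
        sol = branch_and_bound(medium_grouped, budget_s=0.0)
        greedy = construct_greedy(medium_grouped)
        assert sol.objective <= greedy.objective + 1e-9
        assert sol.bound is not None and sol.bound <= sol.objective + 1e-12
        assert audit_solution(sol, medium_grouped) == []

    def test_deterministic_across_runs(self, medium_grouped):
        a = branch_and_bound(medium_grouped, budget_s=1.0, node_limit=20_000)
        b = branch_and_bound(medium_grouped, budget_s=1.0, node_limit=20_000)
        assert a.objective == b.objective
        assert [r.stops for r in a.routes] == [r.stops for r in b.routes]

    def test_vehicle_order_sorts_by_decreasing_index(self, small_grouped):
        order = vehicle_order(small_grouped)
        scores = [
            vehicle_index(small_grouped.instance.vehicles[v], small_grouped.means)
            for v in order
        ]
        assert scores == sorted(scores, reverse=True)
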