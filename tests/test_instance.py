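import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldroute.config import Config
from coldroute.instance import (
    DegenerateInstanceError,
    LookupError_,
    compute_means,
    transit_time,
    transit_time_matrix,
    validate_instance,
)
from coldroute.synth import GeneratorSpec, generate_instance


class TestTransitTime:
    @pytest.mark.parametrize(
        "dist, velocity, expected",
        [(60.0, 60.0, 1.0), (45.0, 30.0, 1.5), (0.0, 50.0, 0.0)],
    )
    def test_is_distance_over_velocity(self, dist, velocity, expected):
        import copy

        from coldroute.synth import fixture_four_centers

        inst = copy.deepcopy(fixture_four_centers())
        inst.roads.distance[0, 1] = dist
        inst.vehicles[0] = dataclasses.replace(inst.vehicles[0], velocity=velocity)
        assert transit_time(inst, 0, 1, 0) == pytest.approx(expected)

    def test_zero_on_diagonal_even_with_nonzero_matrix_entry(self):
        import copy

        from coldroute.synth import fixture_four_centers

        inst = copy.deepcopy(fixture_four_centers())
        inst.roads.distance[2, 2] = 99.0
        assert transit_time(inst, 2, 2, 0) == 0.0
        h = transit_time_matrix(inst)
        assert np.all(np.diagonal(h[:, :, 0]) == 0.0)
        assert (h >= 0).all()

    def test_accepts_names_and_rejects_unknown(self, four_centers):
        assert transit_time(four_centers, "o", "b", "truck") == pytest.approx(0.5)
        with pytest.raises(LookupError_):
            transit_time(four_centers, "o", "nowhere", "truck")
        with pytest.raises(LookupError_):
            transit_time(four_centers, "o", "b", "bus")


class TestComputeMeans:
    def test_two_center_hand_sum(self, four_centers):
        """mu_h on a 1-vehicle, 2-center instance with h=[[0,1],[1,0]] is
        2*(0+1+1+0)/(1*4) = 1."""
        inst = dataclasses.replace(
            four_centers,
            centers=four_centers.centers[:2],
            roads=dataclasses.replace(
                four_centers.roads,
                distance=np.array([[0.0, 60.0], [60.0, 0.0]]),
                condition=four_centers.roads.condition[:2, :2],
                penalty=four_centers.roads.penalty[:2, :2],
                availability=four_centers.roads.availability[:2, :2],
            ),
            demand=four_centers.demand[:2],
        )
        means = compute_means(inst)
        assert means.mu_h == pytest.approx(1.0)
        # factor-2 convention can be disabled
        means_no2 = compute_means(inst, Config(mu_h_factor2=False))
        assert means_no2.mu_h == pytest.approx(0.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_resummation(self, seed):
        inst = generate_instance(GeneratorSpec(n_centers=6, n_vehicles=2, seed=seed))
        means = compute_means(inst)
        n, nv = inst.n_centers, len(inst.vehicles)
        acc = 0.0
        for v, veh in enumerate(inst.vehicles):
            for i in range(n):
                for j in range(n):
                    acc += 2 * (inst.roads.distance[i, j] / veh.velocity if i != j else 0.0)
        assert means.mu_h == pytest.approx(acc / (nv * n * n), abs=1e-12)
        assert means.mu_beta == pytest.approx(
            sum(v.penalty for v in inst.vehicles) / nv, abs=1e-12
        )
        assert means.mu_gamma == pytest.approx(
            float(inst.roads.penalty.sum()) / n**2, abs=1e-12
        )
        assert means.mu_cr == pytest.approx(
            sum(v.cold_capacity for v in inst.vehicles) / nv, abs=1e-12
        )
        assert all(
            x > 0 for x in (means.mu_h, means.mu_gamma, means.mu_beta,
                            means.mu_cr, means.mu_cd, means.mu_v)
        )

    def test_capacity_means_are_simple_averages(self, four_centers):
        import copy

        inst = copy.deepcopy(four_centers)
        v0 = dataclasses.replace(inst.vehicles[0], cold_capacity=40.0)
        v1 = dataclasses.replace(inst.vehicles[0], name="t2", cold_capacity=60.0)
        inst.vehicles = [v0, v1]
        assert compute_means(inst).mu_cr == pytest.approx(50.0)

    def test_degenerate_instance_rejected(self, four_centers):
        inst = dataclasses.replace(four_centers, vehicles=[])
        with pytest.raises(DegenerateInstanceError):
            compute_means(inst)


class TestValidateInstance:
    def test_clean_generated_instance_has_no_findings(self):
        inst = generate_instance(GeneratorSpec(n_centers=8, n_vehicles=2, seed=5))
        assert validate_instance(inst) == []

    def test_missing_depot_is_an_error(self, four_centers):
        import copy

        inst = copy.deepcopy(four_centers)
        inst.centers = [dataclasses.replace(c, is_depot=False) for c in inst.centers]
        findings = validate_instance(inst)
        assert any(f.severity == "error" and "depot" in f.message for f in findings)

    def test_storage_overrun_is_warning_not_error(self, four_centers):
        """Demand above a center's storage must not block solving."""
        import copy

        inst = copy.deepcopy(four_centers)
        inst.centers[1] = dataclasses.replace(inst.centers[1], cold_capacity=0.5)
        findings = validate_instance(inst)
        warnings = [f for f in findings if f.severity == "warning"]
        errors = [f for f in findings if f.severity == "error"]
        assert len(warnings) == 1 and "cold" in warnings[0].message
        assert errors == []

    def test_nonpositive_velocity_and_shape_mismatch_are_errors(self, four_centers):
        import copy

        inst = copy.deepcopy(four_centers)
        inst.vehicles = [dataclasses.replace(inst.vehicles[0], velocity=0.0)]
        inst.demand = inst.demand[:, :1]
        severities = {f.severity for f in validate_instance(inst)}
        assert severities == {"error"}
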