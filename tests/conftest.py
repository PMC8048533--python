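import pytest

from coldroute.config import DEFAULT_CONFIG
from coldroute.preprocess import group_products
from coldroute.synth import (
    GeneratorSpec,
    fixture_four_centers,
    generate_instance,
    oracle_suite_spec,
)


@pytest.fixture(scope="session")
def four_centers():
    return fixture_four_centers()


@pytest.fixture(scope="session")
def four_centers_grouped(four_centers):
    return group_products(four_centers)


@pytest.fixture(scope="session")
def small_instance():
    """A compact solvable district: 5 centers, 2 vehicles."""
    return generate_instance(oracle_suite_spec(seed=3, n_centers=5, n_vehicles=2))


@pytest.fixture(scope="session")
def small_grouped(small_instance):
    return group_products(small_instance)


@pytest.fixture(scope="session")
def medium_instance():
    """District-scale shape: 11 centers, 2 vehicles, 13 products."""
    return generate_instance(GeneratorSpec(n_centers=11, n_vehicles=2, seed=11))


@pytest.fixture(scope="session")
def medium_grouped(medium_instance):
    return group_products(medium_instance)


def oracle_grouped(seed: int, objective_form: str = "printed"):
    """A small instance from the exhaustive-check family, preprocessed."""
    n_centers = 4 + seed % 3
    n_vehicles = 1 + seed % 2
    inst = generate_instance(oracle_suite_spec(seed=seed, n_centers=n_centers, n_vehicles=n_vehicles))
    return group_products(inst, config=DEFAULT_CONFIG.with_form(objective_form))
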