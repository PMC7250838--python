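import pytest

from phyloendemism import SimulationConfig, simulate_dataset, worked_example_fixture


def small_instance(seed, n_species=20, grid_shape=(10, 10), **kwargs):
    """One seeded synthetic (tree, occupancy, pressure-grid) triple."""
    cfg = SimulationConfig(
        n_species=n_species, grid_shape=grid_shape, seed=seed, **kwargs
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def worked_example():
    """The two-branch / three-cell textbook fixture (forest, occ, grid)."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def instance():
    """Factory for seeded synthetic instances."""
    return small_instance
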