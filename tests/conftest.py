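import pytest

from mirevtd import SimulationConfig, simulate_individual_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_per_temp=2, seed=7)


@pytest.fixture(scope="session")
def compliant_ds(small_config):
    """A small compliant individual-level dataset (16 rows)."""
    return simulate_individual_dataset(small_config)


@pytest.fixture()
def ds(compliant_ds):
    """Mutable copy of the compliant dataset for per-test perturbation."""
    return compliant_ds.copy()
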