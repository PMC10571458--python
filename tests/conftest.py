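import pytest

from clonetrace.datasets import load_case
from clonetrace.synthetic import SimulationConfig, simulate_clone_tree, simulate_dataset


@pytest.fixture(scope="session")
def gp5():
    return load_case("GP5")


@pytest.fixture(scope="session")
def gp12():
    return load_case("GP12")


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated read set used across io/clustering tests."""
    config = SimulationConfig(
        seed=11, n_clusters=4, n_samples=4, base_rate=3.0, mean_depth=90.0,
        ccf_noise_sd=0.005,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_tree():
    config = SimulationConfig(seed=23, n_clusters=6, n_samples=6)
    tree, truth = simulate_clone_tree(config)
    return tree, truth
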