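import numpy as np
import pytest

from mitolandscape import simdata
from mitolandscape.haplogroup import EdgeVariant, Haplotree


@pytest.fixture(scope="session")
def chain_tree() -> Haplotree:
    """ROOT -> A (v1=100G) -> A1 (v2=200T) -> A1a (back-mutates v1, adds 300C)."""
    tree = Haplotree(root="ROOT")
    tree.add_edge("ROOT", "A", [EdgeVariant(100, "G")])
    tree.add_edge("A", "A1", [EdgeVariant(200, "T")])
    tree.add_edge(
        "A1", "A1a", [EdgeVariant(100, "G", back_mutation=True), EdgeVariant(300, "C")]
    )
    return tree


@pytest.fixture(scope="session")
def sim_cohort():
    """Medium simulated cohort shared across read-only tests."""
    config = simdata.SimConfig(seed=11, n_samples=400)
    tree = simdata.simulate_haplotree(config)
    matrix, truth = simdata.simulate_mt_cohort(tree, config)
    return config, tree, matrix, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    config = simdata.SimConfig(seed=7, n_samples=300, mutation_rate=0.0)
    tree = simdata.simulate_haplotree(config)
    matrix, truth = simdata.simulate_mt_cohort(tree, config)
    return config, tree, matrix, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
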