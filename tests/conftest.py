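import numpy as np
import pytest

from sparseprs import simulate as sim


@pytest.fixture(scope="session")
def small_dataset():
    """Single-population quantitative dataset shared across read-only tests."""
    cfg = sim.SimulationConfig(
        n_per_population={"dev": 1200},
        m_variants=300,
        n_causal=15,
        h2_true=0.5,
        ld_block_size=5,
        ld_rho=0.3,
        seed=11,
    )
    return sim.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def binary_dataset():
    cfg = sim.SimulationConfig(
        n_per_population={"dev": 1500},
        m_variants=200,
        n_causal=20,
        h2_true=0.5,
        prevalence_K=0.3,
        family="binomial",
        seed=7,
    )
    return sim.simulate_dataset(cfg)


def split_indices(data):
    labels = data.split.to_numpy()
    return tuple(
        np.flatnonzero(labels == name) for name in ("train", "validation", "test")
    )
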