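import numpy as np
import pytest

from mirseq.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study (same design, ~10k reads/sample) for fast tests."""
    return SimulationConfig(seed=3, lib_size_mean=10_000)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One shared synthetic study: (positive, negative, counts, reads,
    target_map, gene_sets, ground_truth)."""
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
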