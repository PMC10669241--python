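import numpy as np
import pytest

from taxonembed.simulate import (
    DEFAULT_HOSTS,
    SimulationConfig,
    generate_corpus,
    generate_taxonomy,
)


@pytest.fixture(scope="session")
def small_tree():
    return generate_taxonomy(DEFAULT_HOSTS, 2, 2, motif_length=8, seed=42)


@pytest.fixture(scope="session")
def small_corpus(small_tree):
    cfg = SimulationConfig(n_sequences=60, length_range=(120, 360), motif_length=8,
                           motif_density=0.6, mutation_rate=0.0, seed=7)
    return generate_corpus(small_tree, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
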