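import numpy as np
import pytest

from mvsl import RunConfig, SynthConfig, generate_dataset, init_state
from mvsl.pipeline import synthetic_protocol


@pytest.fixture(scope="session")
def small_dataset():
    """A 80-gene planted dataset, big enough to train on in seconds."""
    return generate_dataset(SynthConfig(n_genes=80, positive_rate=0.03, seed=7))


@pytest.fixture(scope="session")
def small_protocol():
    """Short training protocol for the 80-gene fixture."""
    return synthetic_protocol(seed=7, max_epochs=150, patience=150)


@pytest.fixture(scope="session")
def small_result(small_dataset, small_protocol):
    """One trained experiment on the small fixture, shared across tests."""
    from mvsl import run_experiment

    return run_experiment(small_dataset, small_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_state(rng):
    """Random weights for a 4-feature model with small layer widths."""
    return init_state(rng, in_dim=4, gcn_dims=(6, 5), head_dims=(8, 6, 4))
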