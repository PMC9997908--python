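import numpy as np
import pytest

from spikeae.bench import preprocess
from spikeae.datasets import SimulationSpec, generate_labeled_spikes


@pytest.fixture(scope="session")
def small_spikes():
    """A modest labeled set (3 units + multi-unit) for fast unit tests."""
    spec = SimulationSpec(
        n_single_units=3, duration=60.0, noise_sd=0.05, multiunit_n_shapes=5
    )
    return generate_labeled_spikes(spec, seed=7)


@pytest.fixture(scope="session")
def prepped_spikes(small_spikes):
    """Aligned, scaled and shuffled version of the small set."""
    return preprocess(small_spikes, shuffle_seed=7)


@pytest.fixture(scope="session")
def easy_clusters():
    """Well-separated 5-cluster set (no multi-unit, low noise), preprocessed."""
    spec = SimulationSpec(
        n_single_units=5, duration=120.0, noise_sd=0.02, multiunit_n_shapes=0
    )
    sp = generate_labeled_spikes(spec, seed=11)
    return preprocess(sp, shuffle_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
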