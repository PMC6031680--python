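import numpy as np
import pytest

from plvnet.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_node_weights():
    """The worked 3-node example used across the graph-metric tests."""
    return np.array([
        [0.0, 0.8, 0.5],
        [0.8, 0.0, 0.2],
        [0.5, 0.2, 0.0],
    ])


@pytest.fixture
def tiny_sim_config():
    """A seconds-scale cohort: 3/4/3 subjects, 8 nodes, 60 trials at 250 Hz.

    60 trials keep the expected number of correct NoGo epochs (~11 per
    subject at the 80/20 split) safely above the two-epoch minimum.
    """
    return SimConfig(
        n_subjects_per_group=(3, 4, 3),
        n_nodes=8,
        n_trials=60,
        sample_rate=250.0,
        seed=7,
    )
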