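import numpy as np
import pytest

from vagalseq import synthetic


@pytest.fixture(scope="session")
def small_config():
    """Small but structurally complete synthetic scene."""
    return synthetic.SynthConfig(n_cells=800, n_trace_cells=60, seed=11)


@pytest.fixture(scope="session")
def cell_scene(small_config):
    return synthetic.generate_cell_table(small_config)


@pytest.fixture(scope="session")
def noiseless_cells():
    cfg = synthetic.SynthConfig(
        n_cells=600, upb_noise_sd=0.0, emb_noise_sd=0.0,
        contaminant_fraction=0.0, seed=5,
    )
    return synthetic.generate_cell_table(cfg)


@pytest.fixture(scope="session")
def trace_scene(small_config):
    return synthetic.generate_trace_set(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
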