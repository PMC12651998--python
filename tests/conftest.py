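import numpy as np
import pytest

import planet


@pytest.fixture(scope="session")
def small_sim_config():
    return planet.SimConfig(n_min=20, n_max=20, tf_fraction=0.3, n_cells=100)


@pytest.fixture(scope="session")
def toy_pair(small_sim_config):
    grn = planet.sample_grn_topology(small_sim_config, seed=7)
    expr = planet.simulate_expression(grn, small_sim_config, seed=8)
    return grn, expr


@pytest.fixture(scope="session")
def tiny_model_config():
    """Desk-scale denoiser used throughout the fast tests."""
    return planet.TriHATConfig(d_x=32, d_e=16, d_t=32, heads=2, gat_heads=2,
                               n_layers=2, edge_groups=2, p_profile=16)


@pytest.fixture(scope="session")
def schedule():
    return planet.cosine_schedule(100, 0.9)
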