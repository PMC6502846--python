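import numpy as np
import pytest

from mackinetics import PoreGeometry, SyntheticConfig, render_movie, simulate_assembly_events


@pytest.fixture(scope="session")
def geometry():
    return PoreGeometry()


@pytest.fixture(scope="session")
def small_noiseless_movie(geometry):
    """20-frame zero-noise movie with 5 pores appearing early (fast initiation)."""
    config = SyntheticConfig(
        n_complexes=5, noise_sd=0.0, t_max=130.0, seed=11, k_init=30.0
    )
    trajectories = simulate_assembly_events(config, geometry)
    movie = render_movie(trajectories, geometry, config)
    return config, trajectories, movie


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
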