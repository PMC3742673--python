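import warnings

import numpy as np
import pytest

import pepmc


@pytest.fixture(scope="session")
def matrix():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pepmc.load_simulated_matrix()


@pytest.fixture(scope="session")
def p1():
    return pepmc.parse_sequence(pepmc.P1, name="P1")


@pytest.fixture(scope="session")
def small_traj(matrix, p1):
    """A short but non-trivial run on a small lattice, reused read-only."""
    cfg = pepmc.SimulationConfig(L=16, C_p=0.1, T=0.7, n_mcs=1000, seed=42)
    return pepmc.run_simulation(cfg, p1, matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
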