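import numpy as np
import pandas as pd
import pytest

from pglearn import Curriculum, PGParams, simulate_pg


@pytest.fixture
def toy_trials() -> pd.DataFrame:
    """Three hand-written trials: contrasts 1.0 / 0 / 0.5, choices R, L, R."""
    return pd.DataFrame({
        "session": [1, 1, 1],
        "trial": [0, 1, 2],
        "contrast_left": [0.0, 0.0, 0.5],
        "contrast_right": [1.0, 0.0, 0.0],
        "correct_side": ["R", "L", "L"],
        "choice": ["R", "L", "R"],
        "reward": [1.0, 1.0, 0.0],
    })


@pytest.fixture(scope="session")
def small_sim():
    """A short vector-PG simulation shared across tests (T = 600)."""
    params = PGParams(variant="vector_pg", alpha=0.08, beta=-0.2,
                      qdiag=0.005, sigma=0.08, sigma_day=0.15)
    cur = Curriculum(n_sessions=3, trials_per_session=200)
    return simulate_pg(params, cur, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
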