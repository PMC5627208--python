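import numpy as np
import pandas as pd
import pytest

from kinclique import synthetic


@pytest.fixture(scope="session")
def scenario():
    return synthetic.make_scenario(seed=7)


@pytest.fixture(scope="session")
def bundle(scenario):
    """Moderate-effort simulated bundle shared across module tests."""
    return synthetic.simulate_all(scenario, n_scans=1200,
                                  n_groom_bouts=1200, n_agonistic=900)


def random_symmetric(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random symmetric labelled matrix with zero diagonal."""
    a = rng.normal(size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    ids = [f"I{k:02d}" for k in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)
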