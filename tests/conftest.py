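import numpy as np
import pytest

import persistlick as pl


@pytest.fixture(scope="session")
def default_session():
    """One default-recipe synthetic session shared across tests."""
    return pl.simulate_session(pl.SessionRecipe(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
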