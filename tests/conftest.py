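import numpy as np
import pytest

from s2trait import build_training_db
from s2trait.season import SeasonConfig, generate_season


@pytest.fixture(scope="session")
def small_db():
    """80-sample simulated training set, fixed seed."""
    return build_training_db(n=80, seed=3)


@pytest.fixture(scope="session")
def season():
    """Canonical synthetic season (9 ESUs, 8 dates, 60x60 grid, seed 0)."""
    return generate_season(SeasonConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
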