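import numpy as np
import pytest

import tdsim


@pytest.fixture(scope="session")
def lex4():
    return tdsim.AttributeLexicon(("sweet", "sour", "bitter", "salty"))


@pytest.fixture(scope="session")
def straw_spec():
    return tdsim.strawberry_like_spec()


@pytest.fixture(scope="session")
def straw_panel(straw_spec):
    """One simulated 17-panelist x 3-replicate strawberry-like study."""
    return tdsim.simulate_panel(straw_spec, 17, 3, seed=20230517)


@pytest.fixture()
def rng():
    return np.random.default_rng(991)
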