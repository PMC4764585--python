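import numpy as np
import pytest

from netdecay.synthdata import EvolParams, evolve_clade


@pytest.fixture(scope="session")
def small_clade():
    """A 200 kb clade with uniform loss hazard, shared across tests."""
    rng = np.random.default_rng(20260928)
    params = EvolParams(loss_rate=0.009)
    return evolve_clade(
        200_000,
        {"sp0": 0.0, "sp50": 50.0, "sp100": 100.0},
        params,
        rng,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
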