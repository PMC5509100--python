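import numpy as np
import pytest
from hypothesis import settings

from deltabind.caller import fit_and_call
from deltabind.synthetic import SimConfig, simulate_scores

settings.register_profile("repro", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_sim():
    """A reduced-size draw from the generator shared across test modules."""
    cfg = SimConfig(n_sites=20_000, seed=11)
    table, labels, latent = simulate_scores(cfg)
    return cfg, table, labels, latent


@pytest.fixture(scope="session")
def small_result(small_sim):
    _, table, _, _ = small_sim
    return fit_and_call(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
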