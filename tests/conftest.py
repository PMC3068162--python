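import numpy as np
import pytest

from eukloc.simulate import WorldConfig, make_tie_fixture, simulate_world


@pytest.fixture(scope="session")
def tie_world():
    return make_tie_fixture()


@pytest.fixture(scope="session")
def small_world():
    """A 40-protein, 4-site world small enough for brute-force re-loops."""
    cfg = WorldConfig(
        n=40,
        C=4,
        G=60,
        signature_terms_per_site=5,
        multiplicity_probs=(0.7, 0.25, 0.05),
        pssm_length_range=(20, 40),
        seed=3,
    )
    return simulate_world(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
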