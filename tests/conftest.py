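import numpy as np
import pytest

from neonovelty.peptides import STANDARD_AA
from neonovelty.synthetic import FixtureConfig, generate_proteome


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_peptide(rng):
    def make(k=9):
        return "".join(rng.choice(list(STANDARD_AA), size=k))

    return make


@pytest.fixture(scope="session")
def small_proteome():
    """Deterministic 10-protein fixture proteome."""
    config = FixtureConfig(n_proteins=10, length_min=60, length_max=120, seed=7)
    return generate_proteome(config)
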