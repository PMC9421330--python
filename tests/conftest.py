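import numpy as np
import pytest
from hypothesis import settings

from noxevo.phylo import SubstitutionModel
from noxevo.simulate import SimulationConfig, make_family_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """The default family fixture (5 clades x 4 leaves, height 0.5)."""
    return make_family_fixture(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def bundle_h03():
    """Family fixture at the moderate divergence used for motif recall."""
    return make_family_fixture(SimulationConfig(height=0.3, seed=0))


@pytest.fixture(scope="session")
def lg_g4():
    return SubstitutionModel("LG", alpha=1.347, k=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
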