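import numpy as np
import pytest

from memqa.synthetic import make_helix_bundle, make_profile, \
    randomize_side_chains


@pytest.fixture(scope="session")
def bundle():
    """A 3-helix, 42-residue membrane bundle (deterministic)."""
    return make_helix_bundle(3, 12, seed=2)


@pytest.fixture(scope="session")
def single_helix():
    return make_helix_bundle(1, 20, seed=1)


@pytest.fixture(scope="session")
def scrambled_bundle(bundle):
    """The bundle with every side chain randomized into likely clashes."""
    return randomize_side_chains(bundle, 1.0, seed=5)


@pytest.fixture(scope="session")
def bundle_profile(bundle):
    return make_profile(bundle, noise_level=0.3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
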