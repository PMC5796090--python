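import numpy as np
import pytest

from memtriage.synthetic import SyntheticSpec, make_toy_structure


@pytest.fixture
def spec():
    return SyntheticSpec(seed=1)


@pytest.fixture
def toy_structure(spec):
    return make_toy_structure(spec)


@pytest.fixture
def small_structure():
    return make_toy_structure(SyntheticSpec(seed=5, n_residues=24))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
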