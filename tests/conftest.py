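import numpy as np
import pytest

from dexaseg.phantom import PhantomParams, generate_arrays


@pytest.fixture(scope="session")
def phantom_arrays():
    """Six desk-scale phantom images (3 subjects x 2 energies) with labels."""
    params = PhantomParams(height=128, width=96, n_subjects=3, seed=0)
    images, labels, sids, energies = generate_arrays(params)
    return images, labels, sids, energies


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
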