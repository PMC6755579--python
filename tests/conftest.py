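import numpy as np
import pytest

from chaosdock.synthetic import make_toy_complex


@pytest.fixture(scope="session")
def toy_rigid():
    """Rigid-ligand toy complex (no torsions)."""
    return make_toy_complex(n_pocket_atoms=24, n_torsions=0, seed=7)


@pytest.fixture(scope="session")
def toy_flex():
    """Flexible toy complex with two rotatable bonds."""
    return make_toy_complex(n_pocket_atoms=26, n_torsions=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
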