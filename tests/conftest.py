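import numpy as np
import pytest

from capsidkit import icosa, lattice


@pytest.fixture(scope="session")
def group():
    return icosa.build_icosahedral_group()


@pytest.fixture(scope="session")
def axes(group):
    return icosa.symmetry_axes(group)


@pytest.fixture(scope="session")
def lattice41():
    return lattice.build_capsid_lattice(lattice.LatticeIndex(4, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(20220923)
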