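import numpy as np
import pytest

from fibrilkit import lattice_enum as le
from fibrilkit.core_builder import LatticeGeometry, build_core_lattice


@pytest.fixture(scope="session")
def alphabet():
    return le.default_alphabet()


@pytest.fixture(scope="session")
def group():
    return le.default_group()


@pytest.fixture(scope="session")
def raw_candidates(alphabet):
    return le.enumerate_raw_candidates(alphabet)


@pytest.fixture(scope="session")
def unique_catalog(raw_candidates, group, alphabet):
    return le.unique_candidates(raw_candidates, group, alphabet)


@pytest.fixture(scope="session")
def survivors(unique_catalog, alphabet):
    return le.apply_strand_uniformity_filter(unique_catalog, alphabet)


@pytest.fixture(scope="session")
def m_candidate(survivors):
    """An M-style architecture: alternating a/b strands within each sheet."""
    return survivors[0]


@pytest.fixture(scope="session")
def geometry():
    return LatticeGeometry()


@pytest.fixture(scope="session")
def core_lattice(m_candidate, alphabet, group, geometry):
    """The reference periodic core build: 40 unit cells, 320 glutamines."""
    return build_core_lattice(m_candidate, alphabet, geometry=geometry,
                              group=group)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
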