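import numpy as np
import pytest

from dyndist.geometry import build_default_duplex, select_constraint_pairs
from dyndist.toymodel import make_harmonic_dimer, make_toy_duplex


@pytest.fixture(scope="session")
def default_duplex():
    """The packaged default: neutralized parallel 13-mer with T7:eA20."""
    return build_default_duplex(seed=1)


@pytest.fixture(scope="session")
def _duplex_system(default_duplex):
    return make_toy_duplex(default_duplex)


@pytest.fixture
def duplex_system(_duplex_system):
    """(topo, conf, site_map) for the toy duplex; conf is a fresh copy."""
    topo, conf, smap = _duplex_system
    return topo, conf.copy(), smap


@pytest.fixture
def equi_spec(default_duplex):
    return select_constraint_pairs(default_duplex, "EQUI")


@pytest.fixture
def dna_spec(default_duplex):
    return select_constraint_pairs(default_duplex, "DNA")


@pytest.fixture
def dimer():
    """Harmonic N–H dimer (k=500 kJ/mol/Å², r0=1 Å)."""
    return make_harmonic_dimer(500.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
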