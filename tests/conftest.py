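import numpy as np
import pytest

from bondforge.architect import place_components
from bondforge.fixtures import (
    FixtureSpec,
    make_coaxial_pair,
    make_f432_fixture,
    make_ideal_oligomer,
    make_mated_pair,
    make_p3_blocks,
)


@pytest.fixture(scope="session")
def o42_pair():
    """Mated O42 cage fixture: (spec, planted dof values)."""
    return make_mated_pair("O42")


@pytest.fixture(scope="session")
def t33_pair():
    return make_mated_pair("T33")


@pytest.fixture(scope="session")
def o42_model(o42_pair):
    spec, dofs = o42_pair
    return place_components(spec, dofs)


@pytest.fixture(scope="session")
def coaxial_pair():
    return make_coaxial_pair(n=3, dz=24.0, dphi=25.0)


@pytest.fixture(scope="session")
def p3_fixture():
    """(block_a, block_b, planted {a, z_off, phi})."""
    return make_p3_blocks(a=90.0, z_off=12.0, phi=20.0)


@pytest.fixture(scope="session")
def f432_fixture():
    """(cage block, linker block, planted {a, cage_radius})."""
    return make_f432_fixture(a=200.0, cage_radius=35.0)


@pytest.fixture
def c3_block():
    return make_ideal_oligomer(FixtureSpec(n=3, monomer_atoms=20))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
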