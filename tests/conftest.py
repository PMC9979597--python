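import numpy as np
import pytest

from cogito.chain_mapper import FattyAcidSpec, build_tag
from cogito.ff_model import canonical_model
from cogito.fixtures import FixtureSpec, build_extended_molecule, build_lamellar

PALMITIC = FattyAcidSpec(16)
OLEIC = FattyAcidSpec(18, ((9, "cis"),))
STEARIC = FattyAcidSpec(18)


@pytest.fixture(scope="session")
def ff():
    return canonical_model()


@pytest.fixture(scope="session")
def post_topology(ff):
    """sn-POSt (palmitoyl / oleoyl / stearoyl): contains all nine bead types."""
    return build_tag("POSt", PALMITIC, OLEIC, STEARIC, ff)


@pytest.fixture(scope="session")
def post_molecule(post_topology, ff):
    return build_extended_molecule(post_topology, ff)


@pytest.fixture(scope="session")
def post_lamellar(post_topology, ff):
    return build_lamellar(
        FixtureSpec(post_topology, 4, "lamellar", lattice=(2, 1, 2)), ff
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
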