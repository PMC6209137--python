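import numpy as np
import pytest

from fluxdesign import make_fixture


@pytest.fixture(scope="session")
def chain():
    return make_fixture("chain")


@pytest.fixture(scope="session")
def branch():
    return make_fixture("branch")


@pytest.fixture(scope="session")
def cycle():
    return make_fixture("cycle")


@pytest.fixture(scope="session")
def all_bundles(chain, branch, cycle):
    return {"chain": chain, "branch": branch, "cycle": cycle}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def pure_mixture(bundle, species_name):
    """Mixture that is 100% one named tracer species of the bundle."""
    from fluxdesign import TracerMixture

    fracs = [1.0 if s.name == species_name else 0.0 for s in bundle.species]
    return TracerMixture(bundle.species, fracs, pool="S_ext")
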