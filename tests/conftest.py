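import numpy as np
import pytest

from convscan import (
    PhyloTree,
    ProteinAlignment,
    equal_rates_model,
    load_empirical_model,
)
from convscan.alphabet import AA_ORDER
from convscan.models import build_rate_matrix


@pytest.fixture(scope="session")
def eq_model():
    return equal_rates_model()


@pytest.fixture(scope="session")
def jtt():
    return load_empirical_model("JTT")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_model(rng):
    """A seeded random reversible model (exchangeabilities + frequencies)."""
    S = rng.random((20, 20))
    S = S + S.T
    np.fill_diagonal(S, 0.0)
    pi = rng.dirichlet(np.ones(20) * 5)
    return build_rate_matrix(S, pi, name="random")


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_newick("((a:0.10,b:0.23):0.08,(c:0.15,d:0.31):0.12);")


def random_alignment(names, length, rng):
    return ProteinAlignment.from_sequences(
        {n: "".join(rng.choice(list(AA_ORDER), size=length)) for n in names}
    )
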