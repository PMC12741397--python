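import numpy as np
import pytest

from mitodate.substmodel import SubstModel
from mitodate.trees import Tree


@pytest.fixture
def jc():
    return SubstModel.jc()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def star3():
    return Tree.from_newick("(A:0.1,B:0.1,C:0.1);")


def random_subst_model(rng, ncat=1, p_inv=0.0):
    """A random valid GTR(+I)+Gamma model (shared by oracle tests)."""
    rates = rng.uniform(0.2, 3.0, size=6)
    freqs = rng.dirichlet(np.full(4, 5.0))
    alpha = float(rng.uniform(0.2, 2.0))
    return SubstModel(rates, freqs, p_inv=p_inv, alpha=alpha, ncat=ncat)
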