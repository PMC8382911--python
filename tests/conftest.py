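"""Shared fixtures: reduced-alphabet models and small reference trees.

Reduced alphabets (2 and 4 states) keep brute-force enumeration oracles
cheap; the Poisson model removes frequency effects where a test wants pure
topology/branch-length behavior.
"""

import numpy as np
import pytest

from haloasr import Tree, poisson_model
from haloasr.models import SubstitutionModel


@pytest.fixture
def poisson2():
    return poisson_model(K=1, alphabet="AR")


@pytest.fixture
def poisson4():
    return poisson_model(K=1, alphabet="ARND")


@pytest.fixture
def poisson4_gamma():
    return poisson_model(alpha=0.7, K=3, alphabet="ARND")


@pytest.fixture
def random_model4():
    """A random valid reversible 4-state model (fixed seed)."""
    rng = np.random.default_rng(1234)
    S = rng.uniform(0.2, 2.0, size=(4, 4))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 0.0)
    pi = rng.dirichlet(np.ones(4) * 5)
    pi = pi / pi.sum()
    return SubstitutionModel(S, pi, alpha=0.8, K=2, alphabet="ARND")


@pytest.fixture
def tree4():
    """Balanced 4-tip tree with distinct branch lengths."""
    return Tree.from_newick("((a:0.1,b:0.25):0.15,(c:0.3,d:0.05):0.2);")


@pytest.fixture
def tree5():
    return Tree.from_newick("(((a:0.1,b:0.2):0.1,c:0.35):0.05,(d:0.15,e:0.4):0.1);")
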