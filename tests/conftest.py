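import numpy as np
import pytest

from paleoniche.trees import TimeTree
from paleoniche.synthgen import SimConfig, simulate_fbd_tree


@pytest.fixture(scope="session")
def three_tip_tree():
    # ((a:1,b:1):2,c:3); shared path of a,b = 2
    return TimeTree.from_newick("((a:1,b:1):2,c:3);")


@pytest.fixture(scope="session")
def five_tip_tree():
    return TimeTree.from_newick("(((a:1,b:1):1,(c:1.5,d:0.5):0.5):1,e:3);")


@pytest.fixture(scope="session")
def medium_tree():
    """40 extant + 10 fossil tips, root near 100 Ma."""
    cfg = SimConfig(seed=11, n_extant=40, n_fossil=10, root_age=100.0,
                    birth_rate=0.05, death_rate=0.02)
    return simulate_fbd_tree(cfg)


@pytest.fixture(scope="session")
def star_tree():
    """Near-star phylogeny: long pendant branches, tiny shared history."""
    n = 12
    parent = [-1] + [0] * n
    blen = [0.0] + [10.0] * n
    labels = [None] + [f"t{i}" for i in range(n)]
    return TimeTree(parent, blen, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
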