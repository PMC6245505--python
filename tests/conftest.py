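import numpy as np
import pytest

from signaldiv.phylo import Phylogeny
from signaldiv.synthetic import gen_tree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def tree5() -> Phylogeny:
    """Small hand-written ultrametric tree (heights in My)."""
    return Phylogeny.from_newick(
        "((A:2,B:2):3,((C:1,D:1):2,E:3):2);"
    )


@pytest.fixture(scope="session")
def tree40() -> Phylogeny:
    """40-tip pure-birth tree at study scale."""
    return gen_tree(40, birth_rate=0.1, seed=7, height=25.0)
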