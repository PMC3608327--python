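import numpy as np
import pytest

from phylinv import Tree


@pytest.fixture
def quartet() -> Tree:
    return Tree.from_newick("((1,2),(3,4));")


@pytest.fixture
def star3() -> Tree:
    return Tree.from_newick("(1,2,3);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
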