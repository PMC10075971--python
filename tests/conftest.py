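import numpy as np
import pytest

from betascape.trees import star_tree, tree_from_string


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def balanced_tree():
    """((A:1,B:1):1,(C:1,D:1):1) — the worked four-tip example."""
    return tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star4():
    return star_tree(["A", "B", "C", "D"], length=1.0)
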