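import numpy as np
import pytest

import chromou as co


@pytest.fixture
def balanced4():
    """Unit-height balanced 4-tip tree with uneven split depths."""
    return co.parse_newick("((A:0.3,B:0.3):0.7,(C:0.6,D:0.6):0.4);")


@pytest.fixture
def cherry3():
    """((A,B),C) with a cherry at depth 0.5."""
    return co.parse_newick("((A:0.5,B:0.5):0.5,C:1);")


@pytest.fixture
def yule():
    """Factory for seeded unit-height pure-birth trees."""

    def _make(n_tips, seed):
        return co.simulate_yule_tree(n_tips, seed)

    return _make


def star_tree(n):
    labels = ",".join(f"t{i}:1" for i in range(n))
    return co.parse_newick(f"({labels});")
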