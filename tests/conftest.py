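import numpy as np
import pytest

from msctree.msc_model import PriorConfig
from msctree.trees_core import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tree3():
    """((A,B),C) with tau_AB = 0.004, tau_root = 0.008, theta = 0.01."""
    return parse_newick("((A:0.004,B:0.004):0.004,C:0.008);", theta=0.01)


@pytest.fixture
def tree5():
    return parse_newick(
        "((((A:0.01,B:0.01):0.01,C:0.02):0.01,D:0.03):0.01,E:0.04);",
        theta=0.01)


@pytest.fixture
def prior():
    return PriorConfig(theta_a=2.0, theta_b=1000.0, tau_a=2.0, tau_b=200.0,
                       tree_prior=1)
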