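import numpy as np
import pytest

from erdosnet.graph import WeightedGraph

SQRT17 = np.sqrt(17.0)


@pytest.fixture
def two_node():
    """Single edge of weight 2; E = 1/w = 0.5 both ways."""
    return WeightedGraph(2, [(0, 1, 2.0)])


@pytest.fixture
def triangle():
    """Unweighted triangle; symmetric fixed point E = sqrt(2)."""
    return WeightedGraph(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])


@pytest.fixture
def path3():
    """Unweighted path 0-1-2; E[1,0]=1, E[0,1]=(sqrt(17)-1)/2, E[0,2]=E[0,1]+1."""
    return WeightedGraph(3, [(0, 1, 1.0), (1, 2, 1.0)])


@pytest.fixture
def star4():
    """Star with centre 0 and leaves 1..3; E[0,leaf]=1, E[leaf,0]=2, E[leaf,leaf']=3."""
    return WeightedGraph(4, [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
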