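import numpy as np
import pytest
import scipy.sparse as sp

from itcwalk.network import (EdgeRecord, assemble_network, column_normalize,
                             TransitionMatrix)


def make_transition(edge_pairs, directed=False, policy="undirected_all",
                    dangling_policy="uniform_jump"):
    records = [EdgeRecord(a, b, "ppi", directed=directed) for a, b in edge_pairs]
    net = assemble_network([records], direction_policy=policy)
    return column_normalize(net, dangling_policy)


def random_transition(n, seed, p=0.1):
    """Connected-ish random undirected network as a transition matrix."""
    rng = np.random.default_rng(seed)
    pairs = [(f"n{i}", f"n{i+1}") for i in range(n - 1)]  # path backbone
    extra = rng.random((n, n)) < p
    pairs += [(f"n{i}", f"n{j}") for i in range(n) for j in range(i + 1, n)
              if extra[i, j]]
    return make_transition(pairs)


@pytest.fixture
def path3():
    """3-node path A-B-C, undirected."""
    return make_transition([("A", "B"), ("B", "C")])


@pytest.fixture
def star6():
    """Star: hub H with 5 leaves."""
    return make_transition([("H", f"L{i}") for i in range(5)])
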