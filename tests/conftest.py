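import numpy as np
import pytest

from phodnet.core_io import OtuTable, SignedNetwork


def make_network(edge_pairs, extra_nodes=(), weight=0.9):
    """SignedNetwork from bare (a, b) pairs; all edges positive unless a
    (a, b, w) triple is given."""
    edges = []
    nodes = set(extra_nodes)
    for e in edge_pairs:
        if len(e) == 2:
            a, b = e
            w = weight
        else:
            a, b, w = e
        edges.append((str(a), str(b), float(w), 1 if w > 0 else -1))
        nodes.update((str(a), str(b)))
    return SignedNetwork(sorted(nodes), edges)


@pytest.fixture
def k3():
    return make_network([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def k4():
    return make_network([(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def p3():
    """Path a-b-c."""
    return make_network([("a", "b"), ("b", "c")])


@pytest.fixture
def s4():
    """Star: hub h with leaves x, y, z."""
    return make_network([("h", "x"), ("h", "y"), ("h", "z")])


@pytest.fixture
def two_triangles():
    return make_network([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


@pytest.fixture
def small_table():
    counts = np.array(
        [
            [5.0, 3.0, 1.0, 1.0],
            [2.0, 2.0, 2.0, 2.0],
            [0.0, 1.0, 4.0, 3.0],
        ]
    )
    return OtuTable(["t1", "t2", "t3"], ["s1", "s2", "s3", "s4"], counts)


@pytest.fixture
def cohesion_fixture():
    """Deterministic 6-taxon × 12-sample count table with mixed positive and
    negative dependence, used for the dual-implementation cohesion check."""
    rng = np.random.default_rng(42)
    grad = np.linspace(0, 1, 12)
    base = np.vstack(
        [
            10 + 40 * grad,
            12 + 35 * grad,
            50 - 38 * grad,
            30 + 5 * np.sin(np.arange(12)),
            20 + rng.normal(0, 3, 12),
            45 - 30 * grad,
        ]
    )
    counts = np.round(np.clip(base + rng.normal(0, 2, base.shape), 0.5, None))
    return OtuTable(
        [f"t{i}" for i in range(6)], [f"s{j}" for j in range(12)], counts
    )
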