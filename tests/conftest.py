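import numpy as np
import pytest

from mkmd import ContactNetwork, RepresentationSet, SynthSpec, planted_multiview_dataset


@pytest.fixture
def path5() -> ContactNetwork:
    return ContactNetwork(5, frozenset([(0, 1), (1, 2), (2, 3), (3, 4)]))


@pytest.fixture
def cycle4() -> ContactNetwork:
    return ContactNetwork(4, frozenset([(0, 1), (1, 2), (2, 3), (0, 3)]))


@pytest.fixture
def triangle() -> ContactNetwork:
    return ContactNetwork(3, frozenset([(0, 1), (1, 2), (0, 2)]))


@pytest.fixture
def single_edge() -> ContactNetwork:
    return ContactNetwork(2, frozenset([(0, 1)]))


@pytest.fixture
def star5() -> ContactNetwork:
    return ContactNetwork(5, frozenset([(0, 1), (0, 2), (0, 3), (0, 4)]))


@pytest.fixture
def complete5() -> ContactNetwork:
    edges = frozenset((i, j) for i in range(5) for j in range(i + 1, 5))
    return ContactNetwork(5, edges)


@pytest.fixture
def edgeless3() -> ContactNetwork:
    return ContactNetwork(3, frozenset())


@pytest.fixture
def random_net() -> ContactNetwork:
    """Seeded 6-node Erdos-Renyi-style graph with at least one edge."""
    rng = np.random.default_rng(42)
    edges = frozenset(
        (i, j) for i in range(6) for j in range(i + 1, 6) if rng.random() < 0.5
    )
    return ContactNetwork(6, edges)


@pytest.fixture(scope="session")
def small_multiview():
    """Small planted dataset shared by fast multi-view tests."""
    spec = SynthSpec(n_per_class=30, seed=5)
    return planted_multiview_dataset(spec)


def random_representation_sets(n: int, dim: int = 3, seed: int = 0, n_views: int = 2):
    rng = np.random.default_rng(seed)
    return [
        RepresentationSet({v: rng.normal(size=dim) for v in range(1, n_views + 1)})
        for _ in range(n)
    ]
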