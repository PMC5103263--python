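import numpy as np
import pytest

from digraphlets import DirectedNetwork, GeneratorConfig, random_digraph


@pytest.fixture
def path_abc():
    """a -> b -> c."""
    return DirectedNetwork.from_arcs_labelled([("a", "b"), ("b", "c")])


@pytest.fixture
def cycle3():
    """Directed 3-cycle a -> b -> c -> a."""
    return DirectedNetwork.from_arcs_labelled([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def reciprocal_triangle():
    """All three dyads reciprocal."""
    pairs = [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b"), ("a", "c"), ("c", "a")]
    return DirectedNetwork.from_arcs_labelled(pairs)


@pytest.fixture
def transitive_triangle():
    """a -> b, a -> c, b -> c."""
    return DirectedNetwork.from_arcs_labelled([("a", "b"), ("a", "c"), ("b", "c")])


@pytest.fixture
def out_star3():
    """Centre c with three pure out-arcs."""
    return DirectedNetwork.from_arcs_labelled([("c", "x"), ("c", "y"), ("c", "z")])


def make_random(n, p_arc, p_rec, seed):
    return random_digraph(GeneratorConfig(seed=seed, n=n, p_arc=p_arc, p_rec=p_rec))


@pytest.fixture
def random_graphs():
    """Small seeded random digraphs spanning sparse to dense regimes."""
    return [
        make_random(n, p_arc, p_rec, seed)
        for seed, (n, p_arc, p_rec) in enumerate(
            [
                (8, 0.2, 0.0),
                (10, 0.4, 0.3),
                (12, 0.6, 0.7),
                (9, 0.9, 1.0),
                (11, 0.5, 0.5),
            ]
        )
    ]
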