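import numpy as np
import pytest

from accperc import (
    AccessibilitySetup,
    build_complete,
    build_complete_no_return,
    build_path,
)


@pytest.fixture(scope="session")
def k2():
    return build_complete(2)


@pytest.fixture(scope="session")
def k2_setup(k2):
    return AccessibilitySetup.homopolymer(k2, "0", "1")


@pytest.fixture(scope="session")
def path3():
    return build_path(3)


@pytest.fixture(scope="session")
def path3_setup(path3):
    return AccessibilitySetup.homopolymer(path3, "0", "2")


@pytest.fixture(scope="session")
def hypercube_graph():
    return build_complete_no_return(2, 0)


def random_reachable_digraph(rng: np.random.Generator, n: int):
    """Random simple digraph on n vertices in which vertex n-1 is reachable
    from vertex 0 (re-drawn until that holds)."""
    from accperc import AlleleGraph

    labels = tuple(str(i) for i in range(n))
    while True:
        A = rng.integers(0, 2, size=(n, n))
        np.fill_diagonal(A, 0)
        g = AlleleGraph(labels, A)
        if g.reachable()[0, n - 1]:
            return g
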