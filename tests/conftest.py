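import pytest

from net3d.graph import Graph


@pytest.fixture
def diamond() -> Graph:
    """Minimal bubble: two 2-edge paths between the same endpoints."""
    g = Graph()
    for u, v in [("s", "a"), ("a", "t"), ("s", "b"), ("b", "t")]:
        g.add_edge(u, v, "arc")
    return g


@pytest.fixture
def backbone_diamond() -> Graph:
    """A diamond whose endpoints continue along a backbone (anchors)."""
    g = Graph()
    for u, v in [("x", "s"), ("s", "a"), ("a", "t"), ("s", "b"), ("b", "t"), ("t", "y")]:
        g.add_edge(u, v, "arc")
    return g


@pytest.fixture
def triangle() -> Graph:
    g = Graph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
        g.add_edge(u, v)
    return g


@pytest.fixture
def path4() -> Graph:
    g = Graph()
    for u, v in [("a", "b"), ("b", "c"), ("c", "d")]:
        g.add_edge(u, v)
    return g


def ring(n: int) -> Graph:
    g = Graph()
    for i in range(n):
        g.add_edge(f"r{i:02d}", f"r{(i + 1) % n:02d}")
    return g
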