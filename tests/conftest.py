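import numpy as np
import pytest

from smrmap.graph import AreaGraph
from smrmap.simulate import SyntheticConfig, simulate_dataset


@pytest.fixture
def path3():
    """Path graph 1-2-3."""
    return AreaGraph.from_edges(["1", "2", "3"], [("1", "2"), ("2", "3")])


@pytest.fixture
def lattice20():
    from smrmap.simulate import make_lattice

    return make_lattice(20, 20)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic study system shared across tests (read-only)."""
    return simulate_dataset(SyntheticConfig(seed=42, nrows=10, ncols=10))


def random_graph(rng: np.random.Generator, n: int, p_edge: float = 0.15) -> AreaGraph:
    """Erdos-Renyi style random area graph."""
    ids = [f"n{i}" for i in range(n)]
    edges = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p_edge
    ]
    return AreaGraph.from_edges(ids, edges)
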