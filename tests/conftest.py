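import networkx as nx
import numpy as np
import pytest

from orbitkit.graphlets import build_catalog


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def random_graphs():
    """A pool of small random graphs spanning sizes and densities."""
    graphs = []
    rng = np.random.default_rng(20260920)
    for n in range(4, 13):
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            for _ in range(5):
                graphs.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    return graphs


def graphlet_index(catalog, pattern: nx.Graph) -> int:
    """Catalog index of the graphlet isomorphic to *pattern*."""
    for gid, g in enumerate(catalog.graphlets):
        if (
            g.number_of_nodes() == pattern.number_of_nodes()
            and g.number_of_edges() == pattern.number_of_edges()
            and nx.is_isomorphic(g, pattern)
        ):
            return gid
    raise AssertionError("pattern is not a catalog graphlet")
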