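import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from ontocode.ontology import OntologyGraph


@pytest.fixture
def chain_graph() -> OntologyGraph:
    """Path ontology D -> C -> B -> A (child -> parent); distances 0..3."""
    return OntologyGraph([("B", "A"), ("C", "B"), ("D", "C")])


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    return OntologyGraph([("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


@pytest.fixture
def tendinitis():
    from ontocode.fixtures import load_fixture

    return load_fixture("tendinitis")


def make_random_dag(rng: np.random.Generator, n: int, max_parents: int = 3) -> OntologyGraph:
    """Random single-rooted DAG built independently of the package generator."""
    codes = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(1, n):
        k = int(rng.integers(1, max_parents + 1))
        for p in rng.choice(i, size=min(k, i), replace=False):
            edges.append((codes[i], codes[int(p)]))
    return OntologyGraph(edges, concepts=codes)


def brute_force_distances(graph: OntologyGraph):
    """All-pairs shortest paths by Floyd-Warshall on the undirected adjacency.

    Independent oracle for the BFS-based distances: returns (codes, matrix)
    where matrix[i, j] is the distance between codes[i] and codes[j]
    (np.inf when unreachable).
    """
    codes = sorted(graph.codes)
    idx = {c: i for i, c in enumerate(codes)}
    adj = np.zeros((len(codes), len(codes)))
    for child, parent in graph.edges:
        adj[idx[child], idx[parent]] = 1
    dist = floyd_warshall(adj, directed=False, unweighted=True)
    return codes, dist
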