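import numpy as np
import pytest

from hme3m import GeneNetwork, SimulationConfig, simulate_pathways


@pytest.fixture(scope="session")
def example_network() -> GeneNetwork:
    """Four compounds A-D, five gene edges, four A->D paths.

    Edges (1-based): 1 A->B, 2 A->B (parallel reaction), 3 B->C, 4 C->D,
    5 B->D.  The path traversing edges [1, 3, 4] is the vector [1,0,1,1,0].
    """
    return GeneNetwork(
        nodes=("A", "B", "C", "D"),
        edges=(("A", "B", "g1"), ("A", "B", "g2"), ("B", "C", "g3"),
               ("C", "D", "g4"), ("B", "D", "g5")),
        start="A",
        end="D",
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small-network benchmark dataset (10% noise), shared across tests."""
    return simulate_pathways(
        SimulationConfig(network_size="small", noise_fraction=0.1, seed=11)
    )


def random_dag_network(rng: np.random.Generator, n_nodes: int) -> GeneNetwork:
    """A random connected layered-ish DAG between a start and an end node.

    Nodes are topologically ordered 0..n-1 with 0 = start, n-1 = end; each
    non-start node gets at least one incoming edge from an earlier node and
    each non-end node at least one outgoing edge to a later node, so every
    node can lie on a start->end path.  Occasional parallel edges exercise
    the multigraph coordinates.
    """
    nodes = tuple(f"v{i}" for i in range(n_nodes))
    edges = []
    for j in range(1, n_nodes):
        i = int(rng.integers(0, j))
        edges.append((nodes[i], nodes[j], ""))
    for i in range(n_nodes - 1):
        if not any(u == nodes[i] for u, _v, _g in edges):
            j = int(rng.integers(i + 1, n_nodes))
            edges.append((nodes[i], nodes[j], ""))
    n_extra = int(rng.integers(0, 2 * n_nodes))
    for _ in range(n_extra):
        i = int(rng.integers(0, n_nodes - 1))
        j = int(rng.integers(i + 1, n_nodes))
        edges.append((nodes[i], nodes[j], ""))
    edges = [(u, v, f"g{t + 1}") for t, (u, v, _) in enumerate(edges)]
    return GeneNetwork(nodes=nodes, edges=tuple(edges), start=nodes[0],
                       end=nodes[-1])


def dfs_path_oracle(network: GeneNetwork, active=None) -> set[bytes]:
    """Independent brute-force recursive DFS enumeration (set of path vectors).

    Written directly against the edge list, without the package's adjacency
    helpers, to serve as an oracle for the production enumerator.
    """
    active = set(range(len(network.edges))) if active is None else set(active)
    found: set[bytes] = set()

    def recurse(node, used_edges, visited):
        if node == network.end:
            vec = np.zeros(len(network.edges), dtype=np.int8)
            vec[list(used_edges)] = 1
            found.add(vec.tobytes())
            return
        for t, (u, v, _g) in enumerate(network.edges):
            if t in active and u == node and v not in visited:
                recurse(v, used_edges + [t], visited | {v})

    if network.start != network.end:
        recurse(network.start, [], {network.start})
    return found
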