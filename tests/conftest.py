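import numpy as np
import pytest

from perturbgraph.graphs import ProxyCausalGraph, ORIGIN_DIRECTED
from perturbgraph.synthdata import SCMParameters


@pytest.fixture
def path_graph():
    """Undirected path a - b - c, doubled into arcs."""
    return ProxyCausalGraph(
        node_ids=("a", "b", "c"),
        arcs=(("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")),
        origin="undirected-doubled",
    )


@pytest.fixture
def chain_scm():
    """Deterministic two-node SCM a -> b with w=2, b_b=-1, noise 0."""
    g = ProxyCausalGraph(node_ids=("a", "b"), arcs=(("a", "b"),),
                         origin=ORIGIN_DIRECTED)
    return SCMParameters(graph=g, weights={("a", "b"): 2.0},
                         biases={"a": 0.3, "b": -1.0}, noise_sd=0.0,
                         topo_order=("a", "b"))


def random_dag(rng: np.random.Generator, n: int, p: float = 0.3):
    """Random DAG over n nodes: forward arcs in a random order."""
    width = len(str(max(n - 1, 1)))
    nodes = tuple(f"v{i:0{width}d}" for i in range(n))
    order = [nodes[i] for i in rng.permutation(n)]
    arcs = tuple(
        (order[i], order[j])
        for i in range(n) for j in range(i + 1, n)
        if rng.random() < p
    )
    return ProxyCausalGraph(node_ids=nodes, arcs=arcs, origin=ORIGIN_DIRECTED), order


def random_undirected(rng: np.random.Generator, n: int, p: float = 0.3):
    """Random undirected (doubled) graph over n nodes."""
    width = len(str(max(n - 1, 1)))
    nodes = tuple(f"v{i:0{width}d}" for i in range(n))
    arcs = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                arcs += [(nodes[i], nodes[j]), (nodes[j], nodes[i])]
    return ProxyCausalGraph(node_ids=nodes, arcs=tuple(arcs),
                            origin="undirected-doubled")
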