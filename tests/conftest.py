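import networkx as nx
import pytest

from netcoherence import (
    EvidenceNetwork,
    EvidenceType,
    FixtureSpec,
    compute_ic,
    make_fixture,
)
from netcoherence.ontology import build_dag


@pytest.fixture
def chain_dag():
    """A <- B <- C (C most specific)."""
    return build_dag([("B", "A"), ("C", "B")])


@pytest.fixture
def diamond_dag():
    """A <- B, A <- C, B <- D, C <- D."""
    return build_dag([("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")])


@pytest.fixture
def small_fixture():
    """50-protein, 5-module coherent fixture used across metric tests."""
    return make_fixture(FixtureSpec(n_proteins=50, n_modules=5, seed=11))


@pytest.fixture
def small_ic(small_fixture):
    return compute_ic(small_fixture.corpus, small_fixture.dag)


def brute_force_ancestors(dag, term):
    """BFS over child->parent edges, independent of OntologyDAG.ancestors."""
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for parent in dag.graph.successors(t):
            if parent not in out:
                out.add(parent)
                frontier.append(parent)
    return out


def network_from_nx(graph: nx.Graph, evidence=EvidenceType.PPI) -> EvidenceNetwork:
    """Wrap a plain networkx graph as a single-evidence network."""
    net = EvidenceNetwork()
    for node in graph.nodes:
        net.add_node(str(node))
    for a, b in graph.edges:
        if a != b:
            net.add_edge(str(a), str(b), {evidence})
    return net
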