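"""Multi-evidence protein relationship networks.

Four evidence layers are supported: co-expression (COE, Pearson |r| above a
threshold), literature co-occurrence (LIT, shared abstracts), experimental
protein-protein interaction (PPI) and sequence similarity (SEQ, BLAST hits
passing E-value and identity cut-offs).  Layers are merged into a combined
network whose edges carry the set of evidence types supporting them, from
which Table-style summaries (evidence-combination counts, transitivity,
components, diameter, orphan counts) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx


class EvidenceType(str, Enum):
    """The four data sources that can justify an edge."""

    COE = "COE"  # gene co-expression
    LIT = "LIT"  # literature co-occurrence
    PPI = "PPI"  # experimental protein-protein interaction
    SEQ = "SEQ"  # sequence similarity

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class EvidenceNetwork:
    """Undirected protein graph; each edge carries a non-empty evidence set.

    Degree-zero nodes (orphans) are legitimate members of the node set so
    orphan counts remain computable.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(self, protein: str) -> None:
        self.graph.add_node(protein)

    def add_edge(self, a: str, b: str, evidence: Iterable[EvidenceType]) -> None:
        if a == b:
            raise ValueError(f"self-loop rejected: {a!r}")
        ev = frozenset(EvidenceType(e) for e in evidence)
        if not ev:
            raise ValueError("edge must carry at least one evidence type")
        if self.graph.has_edge(a, b):
            ev = ev | self.graph.edges[a, b]["evidence"]
        self.graph.add_edge(a, b, evidence=ev)

    def evidence(self, a: str, b: str) -> frozenset[EvidenceType]:
        return self.graph.edges[a, b]["evidence"]

    def edges(self) -> Iterable[tuple[str, str, frozenset[EvidenceType]]]:
        for a, b, data in self.graph.edges(data=True):
            yield a, b, data["evidence"]

    def evidence_types(self) -> frozenset[EvidenceType]:
        """Union of evidence types over all edges."""
        out: set[EvidenceType] = set()
        for _, _, ev in self.edges():
            out |= ev
        return frozenset(out)

    def restrict_to(self, proteins: Iterable[str]) -> "EvidenceNetwork":
        """Subnetwork induced on ``proteins`` (missing ids are added as orphans)."""
        keep = set(proteins)
        sub = nx.Graph()
        sub.add_nodes_from(keep)
        for a, b, data in self.graph.edges(data=True):
            if a in keep and b in keep:
                sub.add_edge(a, b, evidence=data["evidence"])
        return EvidenceNetwork(graph=sub)


def build_coe(
    records: Iterable[tuple[str, str, float]], threshold: float = 0.6
) -> EvidenceNetwork:
    """Co-expression layer: edge iff |r| > threshold (strict).

    The magnitude rule means strong negative correlation also links a pair.
    """
    net = EvidenceNetwork()
    for a, b, r in records:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation out of [-1, 1] for ({a}, {b}): {r}")
        net.add_node(a)
        net.add_node(b)
        if a != b and abs(r) > threshold:
            net.add_edge(a, b, {EvidenceType.COE})
    return net


def build_seq(
    hits: Iterable[Sequence],
    evalue_max: float = 1e-3,
    identity_min: float = 25.0,
) -> EvidenceNetwork:
    """Sequence-similarity layer from BLAST tabular (outfmt 6) rows.

    One undirected edge per protein pair with at least one hit, in either
    direction, with E-value < ``evalue_max`` and identity >= ``identity_min``.
    Self-hits are ignored.
    """
    net = EvidenceNetwork()
    for i, row in enumerate(hits, start=1):
        if len(row) < 12:
            raise ValueError(f"malformed BLAST tabular row at line {i}: "
                             f"expected 12 columns, got {len(row)}")
        query, subject = str(row[0]), str(row[1])
        try:
            identity = float(row[2])
            evalue = float(row[10])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed BLAST tabular row at line {i}: {exc}") from exc
        net.add_node(query)
        net.add_node(subject)
        if query == subject:
            continue
        if evalue < evalue_max and identity >= identity_min:
            net.add_edge(query, subject, {EvidenceType.SEQ})
    return net


def build_lit(counts: Iterable[tuple[str, str, int]]) -> EvidenceNetwork:
    """Literature layer: edge iff the pair shares at least one abstract."""
    net = EvidenceNetwork()
    for a, b, n in counts:
        if n < 0:
            raise ValueError(f"negative abstract count for ({a}, {b}): {n}")
        net.add_node(a)
        net.add_node(b)
        if a != b and n >= 1:
            net.add_edge(a, b, {EvidenceType.LIT})
    return net


def build_ppi(pairs: Iterable[tuple[str, str]]) -> EvidenceNetwork:
    """PPI layer: de-duplicated undirected pairs, self-interactions discarded."""
    net = EvidenceNetwork()
    for a, b in pairs:
        net.add_node(a)
        net.add_node(b)
        if a != b:
            net.add_edge(a, b, {EvidenceType.PPI})
    return net


def merge(
    layers: Sequence[EvidenceNetwork], restrict_to_ppi: bool = False
) -> EvidenceNetwork:
    """Union of evidence layers into a combined network.

    The node set is the union of layer node sets; each edge's evidence set is
    the union of its per-layer memberships.  Two layers may not carry the
    same evidence type.  With ``restrict_to_ppi`` the node universe is fixed
    to the PPI layer's proteins, mirroring a design where interaction data
    defines the reference proteome subset.
    """
    seen: set[EvidenceType] = set()
    ppi_nodes: frozenset[str] | None = None
    for layer in layers:
        types = layer.evidence_types()
        overlap = seen & types
        if overlap:
            raise ValueError(
                f"duplicate evidence type(s) across layers: {sorted(t.value for t in overlap)}"
            )
        seen |= types
        if EvidenceType.PPI in types:
            ppi_nodes = layer.nodes
    combined = EvidenceNetwork()
    for layer in layers:
        for node in layer.nodes:
            combined.add_node(node)
        for a, b, ev in layer.edges():
            combined.add_edge(a, b, ev)
    if restrict_to_ppi:
        if ppi_nodes is None:
            raise ValueError("restrict_to_ppi requires a PPI layer")
        combined = combined.restrict_to(ppi_nodes)
    return combined


@dataclass(frozen=True)
class CombinationTable:
    """Edge counts by evidence combination, exclusive and inclusive.

    ``exclusive[S]`` counts edges whose evidence set is exactly S (a
    partition of the edge set); ``inclusive[S]`` counts edges whose evidence
    set contains S, i.e. the sum of exclusive counts over supersets of S.
    """

    exclusive: dict[frozenset[EvidenceType], int]
    inclusive: dict[frozenset[EvidenceType], int]
    total_edges: int

    def exclusive_percent(self, subset: frozenset[EvidenceType]) -> float:
        if self.total_edges == 0:
            return 0.0
        return 100.0 * self.exclusive.get(subset, 0) / self.total_edges

    def inclusive_percent(self, subset: frozenset[EvidenceType]) -> float:
        if self.total_edges == 0:
            return 0.0
        return 100.0 * self.inclusive.get(subset, 0) / self.total_edges


def all_evidence_subsets() -> list[frozenset[EvidenceType]]:
    """The 15 non-empty subsets of the four evidence types."""
    types = list(EvidenceType)
    out = []
    for k in range(1, 5):
        out.extend(frozenset(c) for c in combinations(types, k))
    return out


def combination_table(net: EvidenceNetwork) -> CombinationTable:
    """Tabulate evidence combinations over the network's edges."""
    subsets = all_evidence_subsets()
    exclusive = {s: 0 for s in subsets}
    for _, _, ev in net.edges():
        exclusive[ev] += 1
    inclusive = {
        s: sum(n for t, n in exclusive.items() if s <= t) for s in subsets
    }
    return CombinationTable(exclusive=exclusive, inclusive=inclusive,
                            total_edges=net.n_edges)


@dataclass(frozen=True)
class GraphProperties:
    """Whole-graph summary statistics.

    Transitivity is 3 x triangles / connected triples; the diameter is the
    unweighted eccentricity maximum over the largest connected component.
    """

    transitivity: float
    n_components: int
    largest_component_size: int
    largest_component_diameter: int
    orphan_count: int


def graph_properties(net: EvidenceNetwork) -> GraphProperties:
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("graph properties of an empty graph are undefined")
    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    if len(largest) >= 2:
        diameter = nx.diameter(g.subgraph(largest))
    else:
        diameter = 0
    return GraphProperties(
        transitivity=nx.transitivity(g),
        n_components=len(components),
        largest_component_size=len(largest),
        largest_component_diameter=diameter,
        orphan_count=sum(1 for n in g.nodes if g.degree(n) == 0),
    )
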