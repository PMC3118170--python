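"""Synthetic ontologies, annotation corpora and modular multi-evidence
networks with known ground truth.

The generator plants a partition of proteins into modules, wires each
evidence layer as a planted-partition graph (edge probability p_in inside a
module, p_out between modules, thinned per layer by an evidence probability)
and annotates each module's proteins to the descendants of a designated
mid-depth ontology term with probability ``annotation_coherence`` (otherwise
to a uniformly random leaf).  Because the clustering ground truth is emitted
alongside, every metric in the package can be exercised against a known
answer without any download.

All randomness flows from one integer seed through per-layer child
generators, so adding a layer does not perturb the draws of earlier layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .mcl import Clustering
from .network import EvidenceNetwork, EvidenceType, merge
from .ontology import AnnotationCorpus, OntologyDAG, build_dag, propagate


def make_toy_dag(depth: int, branching: int) -> OntologyDAG:
    """Deterministic balanced tree plus one diamond term.

    The tree has ``sum_d branching**d`` terms for d = 0..depth; one extra
    term with two parents (both at depth 1 when available) exercises DAG
    (not tree) code paths.  Term ids are GO-style, zero-padded, assigned in
    breadth-first order.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    root = next_id()
    edges: list[tuple[str, str]] = []
    level = [root]
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                child = next_id()
                edges.append((child, parent))
                nxt.append(child)
        level = nxt
    # diamond: one term with two parents
    diamond = next_id()
    if branching >= 2:
        first_level = [e[0] for e in edges[:branching]] if depth >= 1 else [root]
        edges.append((diamond, first_level[0]))
        edges.append((diamond, first_level[1]))
    else:
        edges.append((diamond, root))
        if depth >= 1:
            edges.append((diamond, edges[0][0]))
    return build_dag(edges, namespace="biological_process")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study fixture.

    ``annotation_coherence`` is the probability that a protein is annotated
    to (a descendant of) its module's designated term rather than to a
    uniformly random leaf; 1.0 yields perfectly coherent modules, 0.0 a
    functional null.
    """

    n_proteins: int = 100
    n_modules: int = 5
    module_sizes: tuple[int, ...] | None = None
    p_in: float = 0.9
    p_out: float = 0.05
    annotation_coherence: float = 1.0
    evidence_probs: dict[EvidenceType, float] = field(
        default_factory=lambda: {
            EvidenceType.COE: 0.5,
            EvidenceType.LIT: 0.5,
            EvidenceType.PPI: 0.5,
            EvidenceType.SEQ: 0.5,
        }
    )
    dag_depth: int = 3
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0 <= self.annotation_coherence <= 1:
            raise ValueError("annotation_coherence must lie in [0, 1]")
        if any(not 0 <= p <= 1 for p in self.evidence_probs.values()):
            raise ValueError("evidence probabilities must lie in [0, 1]")
        if self.module_sizes is not None and sum(self.module_sizes) != self.n_proteins:
            raise ValueError("module sizes must sum to n_proteins")

    def sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return tuple(self.module_sizes)
        base, rem = divmod(self.n_proteins, self.n_modules)
        if base == 0:
            raise ValueError("more modules than proteins")
        return tuple(base + (1 if i < rem else 0) for i in range(self.n_modules))


@dataclass(frozen=True)
class Fixture:
    """A generated study fixture with its ground truth."""

    dag: OntologyDAG
    corpus: AnnotationCorpus
    layers: tuple[EvidenceNetwork, ...]
    combined: EvidenceNetwork
    truth: Clustering
    module_terms: tuple[str, ...]
    direct: dict[str, frozenset[str]]


def _dag_levels(dag: OntologyDAG) -> dict[str, int]:
    """Depth of every term (longest path from the root)."""
    levels = {dag.root: 0}
    # child->parent orientation: reversed topological order visits parents first
    order = list(reversed(list(nx.topological_sort(dag.graph))))
    for t in order:
        if t == dag.root:
            continue
        levels[t] = 1 + max(levels[p] for p in dag.parents(t))
    return levels


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a modular multi-evidence fixture, reproducibly from its seed."""
    root_rng = np.random.default_rng(spec.seed)
    # fixed stream order: dag/annotation first, then one child per layer
    children = root_rng.spawn(1 + len(EvidenceType))
    ann_rng = children[0]
    layer_rngs = dict(zip(list(EvidenceType), children[1:]))

    dag = make_toy_dag(spec.dag_depth, spec.dag_branching)
    levels = _dag_levels(dag)
    max_depth = max(levels.values())
    sizes = spec.sizes()
    # designated module terms live at mid depth; fall back deeper (then
    # shallower) when that level is too narrow for the module count
    preferred = max(1, max_depth // 2)
    mid_terms: list[str] = []
    for lvl in sorted(range(1, max_depth + 1), key=lambda l: (abs(l - preferred), -l)):
        candidates = sorted(t for t, d in levels.items() if d == lvl)
        if len(candidates) >= len(sizes):
            mid_terms = candidates
            break
    leaves = sorted(t for t in dag.terms if not dag.children(t))
    if len(mid_terms) < len(sizes):
        raise ValueError(
            f"no DAG level holds {len(sizes)} module terms; "
            "deepen or widen the DAG"
        )
    module_terms = tuple(mid_terms[: len(sizes)])

    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    membership = np.repeat(np.arange(len(sizes)), sizes)
    truth = Clustering.from_iterable(
        [
            {proteins[i] for i in np.flatnonzero(membership == m)}
            for m in range(len(sizes))
        ]
    )

    # annotations: coherent proteins draw from their module term's subtree
    descendants: dict[str, list[str]] = {}
    for t in module_terms:
        below = sorted(u for u in dag.terms if t in dag.ancestors(u))
        descendants[t] = below
    direct: dict[str, frozenset[str]] = {}
    for i, p in enumerate(proteins):
        term_pool = descendants[module_terms[membership[i]]]
        if ann_rng.random() < spec.annotation_coherence:
            term = term_pool[ann_rng.integers(len(term_pool))]
        else:
            term = leaves[ann_rng.integers(len(leaves))]
        direct[p] = frozenset({term})
    corpus = propagate(direct, dag)

    # evidence layers: shared planted partition, thinned independently
    iu, ju = np.triu_indices(spec.n_proteins, k=1)
    same = membership[iu] == membership[ju]
    p_edge = np.where(same, spec.p_in, spec.p_out)
    layers = []
    for ev in EvidenceType:
        rng = layer_rngs[ev]
        keep = spec.evidence_probs.get(ev, 0.0)
        net = EvidenceNetwork()
        for p in proteins:
            net.add_node(p)
        hit = rng.random(iu.size) < p_edge * keep
        for i, j in zip(iu[hit], ju[hit]):
            net.add_edge(proteins[i], proteins[j], {ev})
        layers.append(net)
    combined = merge(layers)
    return Fixture(
        dag=dag,
        corpus=corpus,
        layers=tuple(layers),
        combined=combined,
        truth=truth,
        module_terms=module_terms,
        direct=direct,
    )


def shuffle_annotations(
    direct: dict[str, frozenset[str]], seed: int
) -> dict[str, frozenset[str]]:
    """Permute annotation sets across proteins (functional null control)."""
    rng = np.random.default_rng(seed)
    proteins = sorted(direct)
    values = [direct[p] for p in proteins]
    perm = rng.permutation(len(proteins))
    return {proteins[i]: values[perm[i]] for i in range(len(proteins))}


def dag_to_obo(dag: OntologyDAG) -> str:
    """Serialise a DAG as minimal OBO 1.2 text (round-trips through parse_obo)."""
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {term}")
        lines.append(f"namespace: {dag.namespace}")
        for parent in sorted(dag.parents(term)):
            rel = dag.graph.edges[term, parent].get("relation", "is_a")
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! synthetic term {parent}")
            else:
                lines.append(f"relationship: {rel} {parent} ! synthetic term {parent}")
        lines.append("")
    return "\n".join(lines)
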