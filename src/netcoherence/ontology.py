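"""Gene Ontology handling: DAG parsing, annotation propagation, information
content and most-informative common ancestors.

The ontology is treated one namespace (aspect) at a time as a rooted DAG of
``is_a``/``part_of`` edges.  Annotations obey the true-path rule: a protein
annotated to a term is implicitly annotated to every ancestor, so corpora are
stored both as direct assignments and as their ancestor closure.  Term
specificity is measured by Resnik information content,

    IC(t) = -log( n_t / N ),

where ``n_t`` counts corpus proteins annotated at-or-below ``t`` (via the
propagated sets) and ``N`` is the number of annotated proteins in the
namespace.  The root therefore has IC 0 and IC is monotone non-decreasing
from the root towards the leaves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: annotation-propagating relations (true-path rule)
PROPAGATING_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, missing root)."""


@dataclass(frozen=True)
class OntologyDAG:
    """A single-namespace GO DAG.

    ``graph`` is a directed graph with child -> parent edges restricted to
    ``is_a`` and ``part_of`` relations.  ``root`` is the unique term with no
    outgoing edges.
    """

    graph: nx.DiGraph
    namespace: str
    root: str
    _ancestor_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self.graph.successors(term))

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self.graph.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive ancestor set of ``term`` (includes itself).

        Reflexivity makes every term its own common ancestor, which the MICA
        computation relies on.
        """
        if term not in self.graph:
            raise KeyError(f"unknown term: {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached

    def edges(self) -> Iterable[tuple[str, str]]:
        """Yield (child, parent) pairs."""
        return self.graph.edges()


def _validate_dag(graph: nx.DiGraph, namespace: str) -> str:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        child, parent = cycle[0][0], cycle[0][1]
        raise OntologyError(
            f"ontology contains a cycle; offending edge {child} -> {parent}"
        )
    roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
    if len(roots) != 1:
        raise OntologyError(
            f"namespace {namespace!r} must have exactly one root, found "
            f"{len(roots)}: {sorted(roots)[:5]}"
        )
    return roots[0]


def parse_obo(stream: IO[str] | str, namespace: str = "biological_process") -> OntologyDAG:
    """Parse OBO 1.2 text into the DAG of one namespace.

    Obsolete terms are excluded.  Only ``is_a`` and ``part_of`` edges are
    retained; all other relationship types are dropped.

    Parameters
    ----------
    stream:
        A path or open text handle containing OBO-format text.
    namespace:
        The GO aspect to keep.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    multi = obonet.read_obo(stream, ignore_obsolete=True)
    graph = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        if data.get("namespace", namespace) == namespace:
            graph.add_node(node)
    for child, parent, key in multi.edges(keys=True):
        if key in PROPAGATING_RELATIONS and child in graph and parent in graph:
            graph.add_edge(child, parent, relation=key)
    if graph.number_of_nodes() == 0:
        raise OntologyError(f"no terms found in namespace {namespace!r}")
    root = _validate_dag(graph, namespace)
    return OntologyDAG(graph=graph, namespace=namespace, root=root)


def build_dag(
    edges: Iterable[tuple[str, str]],
    namespace: str = "biological_process",
    relation: str = "is_a",
) -> OntologyDAG:
    """Construct a DAG directly from (child, parent) pairs (used by fixtures)."""
    graph = nx.DiGraph()
    for child, parent in edges:
        graph.add_edge(child, parent, relation=relation)
    root = _validate_dag(graph, namespace)
    return OntologyDAG(graph=graph, namespace=namespace, root=root)


@dataclass(frozen=True)
class AnnotationCorpus:
    """Protein -> GO term assignments, direct and ancestor-propagated."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    unannotated: frozenset[str] = frozenset()

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.propagated)

    @property
    def annotated_proteins(self) -> frozenset[str]:
        return frozenset(p for p, ts in self.propagated.items() if ts)

    def annotated_in(self, proteins: Iterable[str]) -> frozenset[str]:
        """Subset of ``proteins`` carrying at least one propagated term."""
        return frozenset(p for p in proteins if self.propagated.get(p))


def propagate(direct: Mapping[str, Iterable[str]], dag: OntologyDAG) -> AnnotationCorpus:
    """Close direct annotations under the ancestor relation.

    Terms absent from ``dag`` (wrong namespace, typos) are dropped with a
    warning.  Proteins left with no in-namespace term keep an empty set and
    are flagged unannotated.
    """
    direct_clean: dict[str, frozenset[str]] = {}
    prop: dict[str, frozenset[str]] = {}
    unannotated = set()
    dropped: set[str] = set()
    for protein, terms in direct.items():
        kept = frozenset(t for t in terms if t in dag)
        dropped.update(set(terms) - kept)
        direct_clean[protein] = kept
        closure: set[str] = set()
        for t in kept:
            closure |= dag.ancestors(t)
        prop[protein] = frozenset(closure)
        if not closure:
            unannotated.add(protein)
    if dropped:
        logger.warning(
            "dropped %d annotation term(s) not in the %s DAG: %s%s",
            len(dropped), dag.namespace, sorted(dropped)[:5],
            "..." if len(dropped) > 5 else "",
        )
    return AnnotationCorpus(
        direct=direct_clean, propagated=prop, unannotated=frozenset(unannotated)
    )


_LOG_BASES = {"e": math.e, "natural": math.e, "10": 10.0, "2": 2.0}


@dataclass(frozen=True)
class ICTable:
    """Per-term information content over a reference corpus.

    ``counts[t]`` is the number of corpus proteins annotated at-or-below t;
    ``corpus_size`` is the count at the root.  Terms never annotated in the
    corpus carry no IC and are excluded from MICA candidacy.
    """

    ic: dict[str, float]
    counts: dict[str, int]
    corpus_size: int
    log_base: float = math.e

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def get(self, term: str, default: float | None = None) -> float | None:
        return self.ic.get(term, default)


def compute_ic(
    corpus: AnnotationCorpus, dag: OntologyDAG, log_base: float | str = math.e
) -> ICTable:
    """Compute Resnik information content from a propagated corpus.

    The corpus may be larger than the protein set later analysed; it serves
    purely as the reference frequency distribution.
    """
    if isinstance(log_base, str):
        log_base = _LOG_BASES[log_base]
    counts: dict[str, int] = {}
    for terms in corpus.propagated.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    corpus_size = counts.get(dag.root, 0)
    if corpus_size == 0:
        raise ValueError("corpus has no annotated proteins; cannot compute IC")
    denom = math.log(log_base)
    ic = {
        t: -math.log(n / corpus_size) / denom if n < corpus_size else 0.0
        for t, n in counts.items()
    }
    return ICTable(ic=ic, counts=counts, corpus_size=corpus_size, log_base=log_base)


def mica(
    ic: ICTable,
    dag: OntologyDAG,
    proteins: Iterable[str],
    corpus: AnnotationCorpus,
) -> tuple[str, float]:
    """Most Informative Common Ancestor of a protein set.

    Returns the maximal-IC term present in every protein's propagated set
    (ties broken by lexicographic term id).  Terms without a defined IC in
    the reference corpus are not candidates.
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("MICA of an empty protein set is undefined")
    common: set[str] | None = None
    for p in proteins:
        terms = corpus.propagated.get(p, frozenset())
        if not terms:
            raise ValueError(f"protein {p!r} has no propagated annotation")
        common = set(terms) if common is None else common & terms
    candidates = [t for t in common if t in ic]  # type: ignore[union-attr]
    if not candidates:
        raise RuntimeError(
            "no common ancestor with defined IC; corpus/DAG mismatch"
        )
    best = min(candidates, key=lambda t: (-ic.ic[t], t))
    return best, ic.ic[best]
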