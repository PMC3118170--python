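"""Markov Cluster (MCL) algorithm on unweighted protein networks.

MCL simulates random-walk flow on the graph: the column-stochastic transition
matrix is alternately squared (expansion, spreading flow) and raised to an
entrywise power (inflation, sharpening flow), with small entries pruned, until
the matrix reaches a doubly-idempotent limit.  Clusters are read off the
attractor structure of that limit.  The inflation coefficient controls
granularity; higher inflation yields more, smaller clusters.

The implementation is dense numpy and deterministic; it is intended for the
network sizes this package analyses (thousands of nodes), not genome-scale
graphs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import EvidenceNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Clustering:
    """A partition of network nodes into disjoint non-empty modules."""

    clusters: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster in partition")
            if seen & c:
                raise ValueError(
                    f"clusters overlap on {sorted(seen & c)[:5]}"
                )
            seen |= c

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def assignment(self) -> dict[str, int]:
        """Node -> cluster-index map."""
        out: dict[str, int] = {}
        for i, c in enumerate(self.clusters):
            for node in c:
                out[node] = i
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @classmethod
    def from_iterable(cls, clusters: Iterable[Iterable[str]]) -> "Clustering":
        return cls(tuple(frozenset(c) for c in clusters))


class MCLConvergenceWarning(UserWarning):
    """Emitted when MCL stops at max_iter without reaching its fixed point."""


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0.0] = 1.0
    return m / sums


def _clusters_from_limit(m: np.ndarray, nodes: Sequence[str]) -> Clustering:
    """Interpret the (near-)idempotent limit matrix as a partition.

    Attractors are nodes with positive diagonal mass; each attractor's row
    support defines a cluster, and attractors with overlapping support form
    one attractor system.  A non-attractor column is assigned to the system
    holding the largest share of its mass (ties: lexicographically smallest
    attractor id), forcing a true partition.
    """
    n = m.shape[0]
    eps = 1e-9
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # degenerate non-converged state: everything singleton
        return Clustering.from_iterable([{nodes[i]} for i in range(n)])

    # union attractors whose row supports overlap
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    support = {a: np.flatnonzero(m[a] > eps) for a in attractors}
    for a in attractors:
        for b in support[a]:
            if b in support:  # b is also an attractor
                union(a, int(b))

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), []).append(a)

    # assign every column to the system with the largest mass on it
    cluster_of: dict[int, int] = {}
    sys_roots = sorted(systems)
    for j in range(n):
        best_root, best_mass = None, -1.0
        for root in sys_roots:
            mass = float(m[systems[root], j].sum())
            if mass > best_mass + eps:
                best_root, best_mass = root, mass
        if best_mass <= eps:
            # no attractor claims this column (numerical corner): singleton
            cluster_of[j] = -j - 1
        else:
            cluster_of[j] = best_root  # ties already resolved: roots scanned in order
    groups: dict[int, set[str]] = {}
    for j, root in cluster_of.items():
        groups.setdefault(root, set()).add(nodes[j])
    ordered = sorted(groups.values(), key=lambda c: min(c))
    return Clustering.from_iterable(ordered)


def mcl(
    net: EvidenceNetwork,
    inflation: float = 2.8,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> Clustering:
    """Cluster an evidence network with MCL.

    Edges are unweighted (weight 1) regardless of evidence multiplicity, and
    a self-loop of weight 1 is added to every node before normalisation (the
    usual MCL regularisation).  The procedure is deterministic.

    Parameters
    ----------
    inflation:
        Granularity coefficient, must exceed 1.  Default 2.8.
    max_iter, tol, prune:
        Iteration cap, convergence tolerance on the max entrywise change,
        and the threshold below which entries are zeroed after each step.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must exceed 1, got {inflation}")
    nodes = sorted(net.nodes)
    if not nodes:
        raise ValueError("cannot cluster an empty network")
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = np.eye(n)  # self-loops
    for a, b, _ in net.edges():
        i, j = index[a], index[b]
        m[i, j] = m[j, i] = 1.0
    m = _normalize_columns(m)

    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = _normalize_columns(np.power(expanded, inflation))
        inflated[inflated < prune] = 0.0
        inflated = _normalize_columns(inflated)
        change = float(np.max(np.abs(inflated - m)))
        m = inflated
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "clusters read from the last iterate",
            MCLConvergenceWarning,
            stacklevel=2,
        )
    return _clusters_from_limit(m, nodes)
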