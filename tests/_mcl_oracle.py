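"""Reference dense-matrix MCL, written independently of netcoherence.mcl.

Same mathematical procedure (add self-loops, column-normalise, alternate
squaring and entrywise inflation with pruning) but a separate code path and a
different cluster-extraction route: clusters are the connected components of
the symmetrised support graph of the limit matrix.
"""

import networkx as nx
import numpy as np


def mcl_reference(graph: nx.Graph, inflation: float = 2.8, max_iter: int = 100,
                  tol: float = 1e-6, prune: float = 1e-5) -> set[frozenset]:
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v in graph.edges:
        if u != v:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    np.fill_diagonal(a, 1.0)
    a = a / a.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        nxt = np.linalg.matrix_power(a, 2) ** inflation
        colsum = nxt.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        nxt = nxt / colsum
        nxt = np.where(nxt < prune, 0.0, nxt)
        colsum = nxt.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        nxt = nxt / colsum
        if np.abs(nxt - a).max() < tol:
            a = nxt
            break
        a = nxt
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(a > 1e-9)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return {
        frozenset(nodes[i] for i in comp)
        for comp in nx.connected_components(support)
    }
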