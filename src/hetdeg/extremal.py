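"""Reference topologies: the completely heterogeneous graph and its foils.

The completely heterogeneous graph on ``n`` nodes realizes every degree
``1..n-1`` exactly once, except for one degree ``k*`` shared by two nodes
(the pigeonhole forces one repeat).  ``k* = n/2`` for even ``n`` and
``(n-1)/2`` for odd ``n``.

The construction is a threshold graph: label ``n-1`` nodes by their
intended degree ``a = 1..n-1`` and join labels ``a, b`` iff ``a + b >= n``;
a final node ``nu`` is joined to every label ``a >= n - k*``, which gives
``nu`` degree ``k*`` and completes each label's degree to its intended
value.  This materializes the inductive argument that the node of degree
``r`` is adjacent exactly to the nodes of degree ``n-1, n-2, ..., n-r``.

Star, regular (circulant wiring) and complete graphs are provided as the
homogeneous/star comparison points.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

__all__ = [
    "kstar",
    "complete_heterogeneous_graph",
    "star_graph",
    "regular_graph",
    "complete_graph",
]


def kstar(n: int) -> int:
    """Repeated degree of the completely heterogeneous graph on ``n`` nodes."""
    if n < 4:
        raise ValueError("completely heterogeneous graph requires n >= 4")
    return n // 2


def complete_heterogeneous_graph(n: int) -> nx.Graph:
    """Completely heterogeneous graph on ``n`` nodes (``n >= 4``).

    Nodes ``0..n-2`` carry intended degrees ``1..n-1`` (node id = intended
    degree − 1, also stored in the node attribute ``intended_degree``);
    node ``n-1`` is the extra node ``nu`` of degree ``k*``.  The resulting
    degree multiset is ``{1, 2, ..., n-1}`` with ``k*`` occurring twice.
    """
    if n < 4:
        raise ValueError("completely heterogeneous graph requires n >= 4")
    a = np.arange(1, n)  # intended degrees of the labelled nodes
    iu, ju = np.triu_indices(n - 1, k=1)
    mask = a[iu] + a[ju] >= n
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    nu = n - 1
    ks = kstar(n)
    # nu attaches to the k* highest-degree labels: a >= n - k*
    g.add_edges_from((int(lab - 1), nu) for lab in range(n - ks, n))
    nx.set_node_attributes(g, {i: i + 1 for i in range(n - 1)}, "intended_degree")
    g.nodes[nu]["intended_degree"] = ks
    return g


def star_graph(n: int) -> nx.Graph:
    """Star on ``n`` nodes: hub node 0, ``n-1`` leaves."""
    if n < 2:
        raise ValueError("star requires n >= 2")
    return nx.star_graph(n - 1)


def regular_graph(n: int, k: int) -> nx.Graph:
    """``k``-regular circulant graph on ``n`` nodes.

    Requires ``2 <= k <= n-1`` and ``n*k`` even (handshake lemma).
    """
    if not 2 <= k <= n - 1:
        raise ValueError("regular graph requires 2 <= k <= n-1")
    if (n * k) % 2 != 0:
        raise ValueError("n*k must be even (handshake lemma)")
    offsets = list(range(1, k // 2 + 1))
    if k % 2 == 1:
        offsets.append(n // 2)
    return nx.circulant_graph(n, offsets)


def complete_graph(n: int) -> nx.Graph:
    if n < 1:
        raise ValueError("complete graph requires n >= 1")
    return nx.complete_graph(n)
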