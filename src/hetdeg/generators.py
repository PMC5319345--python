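"""Seeded random-graph generators: Erdős–Rényi, preferential attachment,
and a tunable-exponent power-law configuration model.

The preferential-attachment generator follows the growth scheme in which a
seed clique of ``m0`` nodes is grown one node at a time, each new node
attaching ``kmin`` edges to existing nodes with probability proportional to
their current degree; ``kmin`` is by construction the minimum degree of the
output.  The configuration-model generator realizes an (approximately)
prescribed degree exponent ``gamma`` directly by sampling degrees from a
discrete power law on ``[kmin, n-1]`` and stub-matching, then simplifying.
"""

from __future__ import annotations

import random

import networkx as nx
import numpy as np

__all__ = [
    "erdos_renyi",
    "barabasi_albert",
    "powerlaw_configuration",
    "fit_degree_exponent",
]


def erdos_renyi(n: int, p: float, seed: int) -> nx.Graph:
    """G(n, p): each of the ``n(n-1)/2`` pairs is an edge with probability ``p``."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    return nx.fast_gnp_random_graph(n, p, seed=seed)


def barabasi_albert(n: int, kmin: int, seed: int, m0: int | None = None) -> nx.Graph:
    """Preferential-attachment scale-free graph with minimum degree ``kmin``.

    Starts from a complete graph on ``m0`` nodes (default ``max(kmin, 2)``);
    each arriving node attaches to ``kmin`` distinct existing nodes sampled
    without replacement with probability proportional to current degree
    (repeated-nodes urn).  The degree exponent tends to the classic value 3
    for large ``n``.
    """
    if m0 is None:
        m0 = max(kmin, 2)
    if not 2 <= m0 < n:
        raise ValueError("need 2 <= m0 < n")
    if not 1 <= kmin <= m0:
        raise ValueError("need 1 <= kmin <= m0")
    rng = random.Random(seed)
    g = nx.complete_graph(m0)
    # urn holds one entry per half-edge, so uniform draws are degree-proportional
    urn: list[int] = [u for u, v in g.edges() for u in (u, v)]
    for new in range(m0, n):
        targets: set[int] = set()
        while len(targets) < kmin:
            targets.add(urn[rng.randrange(len(urn))])
        g.add_edges_from((new, t) for t in targets)
        urn.extend(targets)
        urn.extend([new] * kmin)
    return g


def powerlaw_configuration(n: int, gamma: float, kmin: int = 1, seed: int = 0) -> nx.Graph:
    """Simple graph with degrees drawn i.i.d. from ``P(k) ∝ k^-gamma``.

    Degrees are sampled on ``[kmin, n-1]``, the sum is made even by
    redrawing one degree, stubs are matched (configuration model) and
    self-loops/parallel edges are dropped.  For ``gamma > 2`` at the sizes
    used here the simplification removes a negligible fraction of edges.
    """
    if gamma <= 1.0:
        raise ValueError("gamma must exceed 1")
    if kmin < 1 or kmin > n - 1:
        raise ValueError("need 1 <= kmin <= n-1")
    rng = np.random.default_rng(seed)
    ks = np.arange(kmin, n, dtype=np.int64)
    w = ks.astype(float) ** (-gamma)
    w /= w.sum()
    degs = rng.choice(ks, size=n, p=w)
    while degs.sum() % 2 != 0:
        degs[rng.integers(n)] = rng.choice(ks, p=w)
    multi = nx.configuration_model(degs.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(multi)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def fit_degree_exponent(g: nx.Graph, kmin: int = 1, bin_factor: float = 1.5) -> float:
    """Estimate the degree exponent ``gamma`` of a heavy-tailed graph.

    Least-squares slope of ``log P(k)`` vs ``log k`` over logarithmic bins
    with ``k >= kmin``; bin counts are normalized by bin width so the fit
    targets the probability density.  Returns the estimated ``gamma``
    (positive for a decaying tail).
    """
    degs = np.array([d for _, d in g.degree() if d >= kmin], dtype=float)
    if degs.size == 0:
        raise ValueError("no degrees >= kmin")
    kmax = degs.max()
    if kmax <= kmin:
        raise ValueError("degenerate degree sequence; exponent undefined")
    edges = [float(kmin)]
    while edges[-1] <= kmax:
        edges.append(edges[-1] * bin_factor)
    edges = np.array(edges)
    counts, _ = np.histogram(degs, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])  # geometric bin centres
    dens = counts / (widths * degs.size)
    keep = dens > 0
    if keep.sum() < 2:
        raise ValueError("too few occupied bins to fit an exponent")
    slope = np.polyfit(np.log(centers[keep]), np.log(dens[keep]), 1)[0]
    return float(-slope)
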