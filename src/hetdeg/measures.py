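"""Degree-distribution heterogeneity indices for unweighted, undirected graphs.

The central quantity is the normalized degree-heterogeneity measure ``Hm``.
For a graph with ``N`` nodes and empirical degree distribution ``P(k)``
(fraction of nodes with degree ``k``), the heterogeneity index is

    h^2 = (1/N) * sum_{k : P(k) > 0} (1 - P(k))^2 ,

i.e. the sum runs only over degrees actually present in the graph (the
*k-spectrum*).  ``h`` is zero for any regular graph (a single degree with
``P = 1``) and grows with the diversity of node degrees.  It is normalized
by the value attained by the *completely heterogeneous* graph on the same
number of nodes — the graph realizing every degree ``1..N-1`` with exactly
one repeated degree — which admits the closed form

    h_het(N)^2 = 1 - 3/N + (N + 2)/N^3 ,

strictly increasing in ``N`` and tending to 1.  The normalized measure

    Hm = h / h_het(N)

lies in ``[0, 1]``: 0 for completely homogeneous (regular) graphs and 1 for
the completely heterogeneous extremal graph.

Classical irregularity indices (degree variance, Albertson, Estrada's
``rho``/``rho_n``, the Randic index) are provided for comparison.  Their
pairwise sums run over *adjacent* node pairs, each undirected edge counted
once: this is the original definition of each index and the unique
convention under which a star graph attains ``rho_n = 1`` and the Randic
bounds ``sqrt(N-1) <= R <= N/2`` are met by the star and regular extremes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeDistribution",
    "HeterogeneityReport",
    "degree_distribution",
    "k_spectrum",
    "heterogeneity_index",
    "h_het_closed_form",
    "h_het_large_n",
    "hm",
    "variance_heterogeneity",
    "albertson_index",
    "estrada_heterogeneity",
    "randic_index",
    "report",
]

_PROB_TOL = 1e-12  # absolute tolerance for sum(P) == 1


@dataclass(frozen=True)
class DegreeDistribution:
    """Empirical degree distribution ``P(k)`` over the observed degrees.

    ``support`` holds the sorted distinct degrees with non-zero count (the
    k-spectrum) and ``probs`` the matching probabilities ``count(k)/N``.
    """

    support: np.ndarray
    probs: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("degree distribution requires at least one node")
        if np.any(self.probs <= 0):
            raise ValueError("all probabilities on the support must be positive")
        if abs(float(self.probs.sum()) - 1.0) > _PROB_TOL:
            raise ValueError("probabilities must sum to 1")
        if np.any(self.support < 0) or np.any(self.support > self.n_nodes - 1):
            raise ValueError("degrees must lie in 0..N-1")


@dataclass(frozen=True)
class HeterogeneityReport:
    """All heterogeneity/irregularity indices for one graph.

    ``estrada_rho``, ``estrada_rho_n`` and ``randic`` are NaN when the graph
    has isolated nodes (``1/sqrt(k)`` undefined); ``h_het`` and ``hm`` are
    NaN for graphs with fewer than 4 nodes, where the normalization is not
    defined.
    """

    n_nodes: int
    h: float
    h_het: float
    hm: float
    variance: float
    albertson: float
    estrada_rho: float
    estrada_rho_n: float
    randic: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _degree_array(g: nx.Graph) -> np.ndarray:
    if g.number_of_nodes() < 1:
        raise ValueError("graph must have at least one node")
    return np.fromiter((d for _, d in g.degree()), dtype=np.int64, count=g.number_of_nodes())


def degree_distribution(g: nx.Graph) -> DegreeDistribution:
    """Empirical ``P(k)`` of ``g``; isolated nodes contribute degree 0."""
    degs = _degree_array(g)
    support, counts = np.unique(degs, return_counts=True)
    return DegreeDistribution(support=support, probs=counts / degs.size, n_nodes=degs.size)


def k_spectrum(g: nx.Graph) -> list[int]:
    """Sorted distinct degrees present in ``g`` (the discrete line spectrum)."""
    return [int(k) for k in degree_distribution(g).support]


def heterogeneity_index(g: nx.Graph) -> float:
    """Degree-heterogeneity index ``h``; 0 for regular graphs.

    The sum runs only over degrees with non-zero probability.
    """
    dist = degree_distribution(g)
    return math.sqrt(float(np.sum((1.0 - dist.probs) ** 2)) / dist.n_nodes)


def h_het_closed_form(n: int) -> float:
    """``h`` of the completely heterogeneous graph on ``n`` nodes (closed form).

    Equals ``sqrt(1 - 3/n + (n + 2)/n**3)``; strictly increasing in ``n``
    and tending to 1 as ``n -> inf``.  Defined for ``n >= 4``, where the
    extremal construction exists.
    """
    if n < 4:
        raise ValueError("completely heterogeneous normalization requires n >= 4")
    return math.sqrt(1.0 - 3.0 / n + (n + 2.0) / n**3)


def h_het_large_n(n: int) -> float:
    """First-order large-``n`` approximation ``sqrt(1 - 3/n)``.

    Documented helper only; the exact closed form is always used for the
    normalization of :func:`hm`.
    """
    if n < 4:
        raise ValueError("requires n >= 4")
    return math.sqrt(1.0 - 3.0 / n)


def hm(g: nx.Graph) -> float:
    """Normalized degree-heterogeneity measure ``Hm = h / h_het(N)`` in [0, 1]."""
    n = g.number_of_nodes()
    if n < 4:
        raise ValueError("Hm requires a graph with at least 4 nodes")
    value = heterogeneity_index(g) / h_het_closed_form(n)
    if value > 1.0 + 1e-9:
        logger.warning("Hm = %.6g exceeds 1; degree support outside 0..N-1?", value)
    return value


def variance_heterogeneity(g: nx.Graph) -> float:
    """Population variance of the degree sequence."""
    degs = _degree_array(g)
    return float(np.mean((degs - degs.mean()) ** 2))


def albertson_index(g: nx.Graph) -> int:
    """Albertson irregularity: sum over edges of ``|k_i - k_j|``."""
    _degree_array(g)  # validates non-empty
    deg = dict(g.degree())
    return int(sum(abs(deg[u] - deg[v]) for u, v in g.edges()))


def _require_no_isolates(g: nx.Graph, what: str) -> dict:
    deg = dict(g.degree())
    if any(d == 0 for d in deg.values()):
        raise ValueError(f"{what} is undefined for graphs with isolated nodes")
    return deg


def estrada_heterogeneity(g: nx.Graph) -> tuple[float, float]:
    """Estrada's irregularity ``rho`` and its normalization ``rho_n``.

    ``rho = sum over edges of (k_i**-0.5 - k_j**-0.5)**2`` and
    ``rho_n = rho / (N - 2*sqrt(N-1))``, which equals 1 for a star graph.
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("rho_n requires at least 3 nodes")
    deg = _require_no_isolates(g, "Estrada heterogeneity")
    rho = sum((deg[u] ** -0.5 - deg[v] ** -0.5) ** 2 for u, v in g.edges())
    rho_n = rho / (n - 2.0 * math.sqrt(n - 1.0))
    return float(rho), float(rho_n)


def randic_index(g: nx.Graph) -> float:
    """Randic connectivity index: sum over edges of ``(k_i * k_j)**-0.5``.

    Bounded by ``sqrt(N-1) <= R <= N/2`` with equality at the star and at
    regular graphs respectively.
    """
    deg = _require_no_isolates(g, "Randic index")
    return float(sum((deg[u] * deg[v]) ** -0.5 for u, v in g.edges()))


def report(g: nx.Graph) -> HeterogeneityReport:
    """Compute every index for ``g`` in one pass.

    Indices whose preconditions the graph violates come back as NaN rather
    than raising, so that batch reporting over arbitrary inputs works.
    """
    n = g.number_of_nodes()
    h = heterogeneity_index(g)
    if n >= 4:
        hh = h_het_closed_form(n)
        hm_val = h / hh
    else:
        hh = hm_val = float("nan")
    try:
        rho, rho_n = estrada_heterogeneity(g)
    except ValueError:
        rho = rho_n = float("nan")
    try:
        rnd = randic_index(g)
    except ValueError:
        rnd = float("nan")
    return HeterogeneityReport(
        n_nodes=n,
        h=h,
        h_het=hh,
        hm=hm_val,
        variance=variance_heterogeneity(g),
        albertson=albertson_index(g),
        estrada_rho=rho,
        estrada_rho_n=rho_n,
        randic=rnd,
    )
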