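"""Recurrence networks from scalar time series.

A scalar series is delay-embedded into ``m`` dimensions with delay ``tau``
(the first minimum of the autocorrelation for flows, 1 for maps), each
coordinate is min–max rescaled to [0, 1], and every embedded point becomes
a node; two nodes are joined iff the distance between their points is at
most a recurrence threshold ``epsilon``.  The default distance is the
maximum (Chebyshev) norm on the rescaled attractor, which keeps ``epsilon``
comparable across embedding dimensions.

``epsilon`` defaults to the *connectivity criterion*: the smallest value at
which the network's giant component covers at least half of the nodes,
i.e. the percolation transition of the recurrence network, which is the
standard prescription for the sparsest network that still represents the
attractor as a whole.  Demanding a larger
giant-component coverage (the ``coverage`` parameter) forces epsilon to
bridge the sparsest outlying regions of the attractor and inflates the
degrees of the dense core.  An edge-density (recurrence-rate) criterion is
available as an alternative.  Temporal neighbors are not excluded (no
Theiler window) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from . import measures
from .dynamics import TimeSeries
from .measures import HeterogeneityReport

__all__ = [
    "EmbeddedAttractor",
    "RNResult",
    "first_acf_minimum",
    "delay_embed",
    "build_rn",
    "select_epsilon",
    "hm_from_series",
    "rn_pipeline",
    "EpsilonSelectionError",
]

_NORMS = {"max": "chebyshev", "euclidean": "euclidean"}


class EpsilonSelectionError(RuntimeError):
    """Raised when the requested epsilon criterion cannot be met."""


@dataclass(frozen=True)
class EmbeddedAttractor:
    """Delay-embedded point cloud: ``points`` has shape (n_points, m)."""

    points: np.ndarray
    m: int
    tau: int
    rescaled: bool

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class RNResult:
    """Full output of the series -> recurrence-network pipeline."""

    report: HeterogeneityReport
    graph: nx.Graph
    m: int
    tau: int
    epsilon: float
    n_nodes: int


def _acf(x: np.ndarray, nlags: int) -> np.ndarray:
    x = x - x.mean()
    n = x.size
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[: nlags + 1]
    return acov / acov[0]


def first_acf_minimum(ts: TimeSeries | np.ndarray) -> int:
    """First local minimum of the autocorrelation function.

    Returns the smallest lag ``l >= 1`` with ``acf(l) < acf(l-1)`` and
    ``acf(l) < acf(l+1)``; the search is capped at one tenth of the series
    length.  If the ACF falls inside the sampling-noise band (3/sqrt(n))
    for two consecutive lags before any interior minimum appears — the
    behaviour of strongly mixing maps and white noise — the current lag is
    returned, which gives 1 for i.i.d. series.
    """
    x = np.asarray(ts.values if isinstance(ts, TimeSeries) else ts, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples to estimate the delay")
    if np.std(x) == 0:
        raise ValueError("constant series has no autocorrelation minimum")
    cap = n // 10
    acf = _acf(x, cap + 1)
    band = 3.0 / math.sqrt(n)
    for lag in range(1, cap):
        if acf[lag] < acf[lag - 1] and acf[lag] < acf[lag + 1]:
            return lag
        if abs(acf[lag]) < band and abs(acf[lag + 1]) < band:
            return lag
    return cap


def delay_embed(ts: TimeSeries | np.ndarray, m: int, tau: int,
                rescale: bool = True) -> EmbeddedAttractor:
    """Embed a scalar series: point ``t`` is ``(x_t, x_{t+tau}, ..., x_{t+(m-1)tau})``.

    Coordinates are min–max rescaled to [0, 1] unless ``rescale=False``.
    """
    x = np.asarray(ts.values if isinstance(ts, TimeSeries) else ts, dtype=float)
    if m < 1 or tau < 1:
        raise ValueError("need m >= 1 and tau >= 1")
    n_pts = x.size - (m - 1) * tau
    if n_pts < 1:
        raise ValueError("series too short for the requested embedding")
    pts = np.column_stack([x[i * tau: i * tau + n_pts] for i in range(m)])
    if rescale:
        lo = pts.min(axis=0)
        span = pts.max(axis=0) - lo
        if np.any(span == 0):
            raise ValueError("constant coordinate; cannot rescale to the unit cube")
        pts = (pts - lo) / span
    return EmbeddedAttractor(points=pts, m=m, tau=tau, rescaled=rescale)


def _condensed_distances(att: EmbeddedAttractor, norm: str) -> np.ndarray:
    try:
        metric = _NORMS[norm]
    except KeyError:
        raise ValueError(f"unknown norm {norm!r}; use 'max' or 'euclidean'") from None
    return pdist(att.points, metric=metric)


def build_rn(att: EmbeddedAttractor, epsilon: float, norm: str = "max") -> nx.Graph:
    """epsilon-recurrence network: edge iff ``d_ij <= epsilon`` for ``i != j``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = att.n_points
    d = _condensed_distances(att, norm)
    iu, ju = np.triu_indices(n, k=1)
    mask = d <= epsilon
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    return g


class _UnionFind:
    __slots__ = ("parent", "size", "max_size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.max_size = 1 if n else 0

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        if self.size[ra] > self.max_size:
            self.max_size = self.size[ra]


def select_epsilon(att: EmbeddedAttractor, criterion: str = "connectivity",
                   rate: float | None = None, norm: str = "max",
                   grid_step: float | None = None, coverage: float = 0.5) -> float:
    """Choose the recurrence threshold.

    ``connectivity`` (default): smallest epsilon at which the giant
    component holds at least ``coverage`` of the nodes; the default
    coverage of one half places epsilon exactly at the percolation
    transition of the recurrence network.  ``grid_step`` optionally rounds
    the threshold up to a fixed grid (e.g. 0.01); the default returns the
    exact transition distance, which avoids quantization jumps in sparse
    networks where the threshold is comparable to the grid step.
    ``recurrence_rate``: epsilon achieving edge density ``rate`` exactly (an
    order statistic of the pairwise distances).
    """
    n = att.n_points
    if n < 2:
        raise ValueError("need at least 2 points to select epsilon")
    d = _condensed_distances(att, norm)
    if criterion == "connectivity":
        target = math.ceil(coverage * n)
        iu, ju = np.triu_indices(n, k=1)
        order = np.argsort(d, kind="stable")
        uf = _UnionFind(n)
        for idx in order:
            uf.union(int(iu[idx]), int(ju[idx]))
            if uf.max_size >= target:
                d_star = float(d[idx])
                if grid_step is None:
                    return d_star
                return round(math.ceil(d_star / grid_step - 1e-9) * grid_step, 10)
        raise EpsilonSelectionError(
            f"giant component never reached {coverage:.0%} of {n} nodes")
    if criterion == "recurrence_rate":
        if rate is None or not 0.0 < rate < 1.0:
            raise ValueError("recurrence_rate criterion needs rate in (0, 1)")
        k = max(1, int(round(rate * d.size)))
        return float(np.partition(d, k - 1)[k - 1])
    raise ValueError(f"unknown criterion {criterion!r}")


def rn_pipeline(ts: TimeSeries, m: int = 3, tau: int | None = None,
                epsilon: float | None = None, criterion: str = "connectivity",
                rate: float | None = None, norm: str = "max",
                n_nodes: int | None = None) -> RNResult:
    """Full pipeline: delay -> embedding -> epsilon -> network -> measures.

    ``tau`` defaults to the first ACF minimum for flows; for maps and other
    unit-interval series (``ts.dt == 1``) it is fixed at 1, since ACF minima
    are ill-defined for strongly mixing maps.  If ``n_nodes`` is given the
    series is truncated so the network has exactly that many nodes.
    """
    if tau is None:
        tau = 1 if ts.dt == 1.0 else first_acf_minimum(ts)
    values = ts.values
    if n_nodes is not None:
        need = n_nodes + (m - 1) * tau
        if values.size < need:
            raise ValueError(
                f"series of length {values.size} too short for {n_nodes} nodes "
                f"at m={m}, tau={tau} (need {need})")
        values = values[:need]
    att = delay_embed(values, m=m, tau=tau)
    if epsilon is None:
        epsilon = select_epsilon(att, criterion=criterion, rate=rate, norm=norm)
    g = build_rn(att, epsilon, norm=norm)
    return RNResult(report=measures.report(g), graph=g, m=m, tau=tau,
                    epsilon=float(epsilon), n_nodes=att.n_points)


def hm_from_series(ts: TimeSeries, m: int = 3, tau: int | None = None,
                   epsilon: float | None = None, criterion: str = "connectivity",
                   rate: float | None = None, norm: str = "max",
                   n_nodes: int | None = None) -> HeterogeneityReport:
    """Heterogeneity report of the recurrence network built from ``ts``."""
    return rn_pipeline(ts, m=m, tau=tau, epsilon=epsilon, criterion=criterion,
                       rate=rate, norm=norm, n_nodes=n_nodes).report
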