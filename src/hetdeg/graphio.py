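"""Readers and writers: edge lists, GML, one-column time series, CSV reports.

Edge lists are whitespace- or comma-delimited, two labels per line, with
``#`` comments.  Node labels may be arbitrary strings or integers; they are
mapped to contiguous internal ids ``0..N-1`` in first-seen order, with the
original labels kept in ``g.graph["label_map"]``.  Duplicate edges and
self-loops are dropped and counted (``g.graph["n_duplicate_edges"]``,
``g.graph["n_self_loops"]``), with a logged warning.  Isolated nodes can
only enter via an explicit node count, in which case labels must be
integers below that count.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import TimeSeries
from .measures import HeterogeneityReport

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_gml",
    "read_series",
    "write_series",
    "write_report_csv",
]


def read_edge_list(path, n_nodes: int | None = None) -> nx.Graph:
    """Parse an edge-list file into a simple undirected graph.

    With ``n_nodes`` the graph has exactly that many nodes (ids 0..n-1) and
    labels must be integers in range — this is the only way isolated nodes
    can be represented.  Without it, labels are arbitrary and mapped to
    0..N-1 in first-seen order.
    """
    path = Path(path)
    g = nx.Graph()
    label_to_id: dict[str, int] = {}
    n_dup = n_self = 0
    if n_nodes is not None:
        g.add_nodes_from(range(n_nodes))

    def node_id(token: str, lineno: int) -> int:
        if n_nodes is not None:
            try:
                i = int(token)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: label {token!r} is not an integer "
                    f"(required when a node count is given)") from None
            if not 0 <= i < n_nodes:
                raise ValueError(f"{path}:{lineno}: node id {i} outside 0..{n_nodes - 1}")
            return i
        if token not in label_to_id:
            label_to_id[token] = len(label_to_id)
            g.add_node(label_to_id[token])
        return label_to_id[token]

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(tokens)}")
            u, v = (node_id(t, lineno) for t in tokens)
            if u == v:
                n_self += 1
            elif g.has_edge(u, v):
                n_dup += 1
            else:
                g.add_edge(u, v)
    if n_dup or n_self:
        logger.warning("%s: dropped %d duplicate edge(s) and %d self-loop(s)",
                       path, n_dup, n_self)
    g.graph["n_duplicate_edges"] = n_dup
    g.graph["n_self_loops"] = n_self
    g.graph["label_map"] = {i: lab for lab, i in label_to_id.items()} if n_nodes is None \
        else {i: str(i) for i in range(n_nodes)}
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write one ``u v`` line per edge (internal/original node names as-is)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# nodes: {g.number_of_nodes()}  edges: {g.number_of_edges()}\n")
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


def read_gml(path) -> nx.Graph:
    """Read a GML file and convert it to a simple graph on ids 0..N-1."""
    raw = nx.read_gml(Path(path), label="id")
    g = nx.Graph()
    nodes = list(raw.nodes())
    mapping = {lab: i for i, lab in enumerate(nodes)}
    g.add_nodes_from(range(len(nodes)))
    n_self = 0
    for u, v in raw.edges():
        if u == v:
            n_self += 1
            continue
        g.add_edge(mapping[u], mapping[v])
    g.graph["label_map"] = {i: str(lab) for lab, i in mapping.items()}
    g.graph["n_self_loops"] = n_self
    return g


def write_series(ts: TimeSeries, path) -> None:
    """One sample per line, with a JSON metadata sidecar at ``<path>.meta.json``."""
    path = Path(path)
    np.savetxt(path, ts.values, fmt="%.17g")
    meta = {"system": ts.system, "dt": ts.dt, **ts.meta}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1, default=str))


def read_series(path, dt: float | None = None) -> TimeSeries:
    """Read a one-column series; dt/system come from the sidecar if present."""
    path = Path(path)
    values = np.loadtxt(path, dtype=float, ndmin=1)
    meta_path = Path(str(path) + ".meta.json")
    system, meta = "unknown", {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        system = meta.pop("system", "unknown")
        if dt is None:
            dt = meta.pop("dt", None)
        else:
            meta.pop("dt", None)
    return TimeSeries(values=values, dt=float(dt) if dt is not None else 1.0,
                      system=system, meta=meta)


def write_report_csv(reports: dict[str, HeterogeneityReport], path) -> pd.DataFrame:
    """One row per named graph with every heterogeneity index; returns the frame."""
    frame = pd.DataFrame(
        [{"name": name, **rep.as_dict()} for name, rep in reports.items()])
    frame.to_csv(path, index=False, float_format="%.6g")
    return frame
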