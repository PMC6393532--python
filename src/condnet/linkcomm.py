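"""Link-community module detection.

Modules are communities of *edges*: edges sharing a node are similar
when the inclusive neighborhoods of their unshared endpoints overlap
(Jaccard), a single-linkage dendrogram is built over 1 - similarity, and
the cut maximizing partition density is kept.  Multi-edges (the same
gene pair supported by different sample clusters) collapse to one simple
edge for detection; labels propagate back to every parallel
condition-edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .threshold import ConditionNetwork

__all__ = [
    "LinkCommunityPartition",
    "edge_similarity",
    "detect_modules",
    "module_gene_sets",
]


@dataclass
class LinkCommunityPartition:
    """Edge -> module assignment at the maximum-partition-density cut.

    ``edge_modules`` maps each simple edge (canonical node pair) to a
    module label like ``"TM0001"`` (decreasing size order) or ``None``
    for edges in groups below the minimum module size.  ``density`` is
    the partition density of the chosen cut, computed before the
    min-size filter.
    """

    edge_modules: dict[tuple[str, str], str | None]
    module_edges: dict[str, int] = field(default_factory=dict)
    module_nodes: dict[str, int] = field(default_factory=dict)
    density: float = 0.0
    cut_height: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "module": m if m is not None else "NA"}
            for (a, b), m in self.edge_modules.items()
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "module"])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": list(self.module_edges),
                "n_edges": list(self.module_edges.values()),
                "n_nodes": [self.module_nodes[m] for m in self.module_edges],
            }
        )


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _as_graph(net) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    if isinstance(net, ConditionNetwork):
        return net.simple_graph()
    g = nx.Graph()
    g.add_edges_from(net)
    return g


def edge_similarity(net, edge_i: tuple[str, str], edge_j: tuple[str, str]) -> float:
    """Inclusive-neighborhood Jaccard between two edges.

    For edges (i, k) and (j, k) sharing node k the similarity is
    ``|n+(i) & n+(j)| / |n+(i) | n+(j)|`` with ``n+(x) = {x} | N(x)``.
    Edges sharing no node have similarity 0 by convention; identical
    edges have similarity 1.
    """
    g = _as_graph(net)
    si, sj = set(edge_i), set(edge_j)
    shared = si & sj
    if not shared:
        return 0.0
    if len(shared) == 2:
        return 1.0
    (i,) = si - shared
    (j,) = sj - shared
    ni = {i} | set(g.neighbors(i))
    nj = {j} | set(g.neighbors(j))
    return len(ni & nj) / len(ni | nj)


def partition_density_term(m_c: int, n_c: int) -> float:
    """One module's contribution m_c * (m_c - (n_c - 1)) / ((n_c - 2)(n_c - 1)).

    Tree-like or smaller groups (n_c <= 2, or m_c = n_c - 1) contribute 0.
    """
    if n_c <= 2:
        return 0.0
    return m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1))


def _partition_density(edges: list[tuple[str, str]], labels: np.ndarray) -> float:
    total = len(edges)
    if total == 0:
        return 0.0
    acc = 0.0
    for lbl in np.unique(labels):
        idx = np.flatnonzero(labels == lbl)
        nodes = {n for i in idx for n in edges[i]}
        acc += partition_density_term(len(idx), len(nodes))
    return 2.0 / total * acc


def detect_modules(net, min_module_edges: int = 3) -> LinkCommunityPartition:
    """Single-linkage link communities cut at maximum partition density.

    Candidate cuts are the dendrogram's unique merge heights (plus the
    all-singletons cut); ties at equal height merge simultaneously; among
    equally dense cuts the lowest (finest) is kept.  Groups with fewer
    than ``min_module_edges`` edges are unassigned.  Modules are labeled
    ``TM0001``, ``TM0002``, ... in decreasing edge-count order.
    """
    g = _as_graph(net)
    edges = sorted(_canonical_edge(a, b) for a, b in g.edges())
    m = len(edges)
    if m == 0:
        raise ValueError("no edges to partition")
    if m == 1:
        labels = np.zeros(1, dtype=int)
        best_h = 0.0
    else:
        neighborhoods = {v: {v} | set(g.neighbors(v)) for v in g.nodes}
        dist = np.ones((m, m))
        incident: dict[str, list[int]] = {}
        for idx, (a, b) in enumerate(edges):
            incident.setdefault(a, []).append(idx)
            incident.setdefault(b, []).append(idx)
        for node, elist in incident.items():
            for ii in range(len(elist)):
                for jj in range(ii + 1, len(elist)):
                    e1, e2 = edges[elist[ii]], edges[elist[jj]]
                    (i,) = set(e1) - {node}
                    (j,) = set(e2) - {node}
                    ni, nj = neighborhoods[i], neighborhoods[j]
                    s = len(ni & nj) / len(ni | nj)
                    d = 1.0 - s
                    if d < dist[elist[ii], elist[jj]]:
                        dist[elist[ii], elist[jj]] = d
                        dist[elist[jj], elist[ii]] = d
        np.fill_diagonal(dist, 0.0)
        z = hierarchy.linkage(squareform(dist, checks=False), method="single")
        heights = np.unique(np.concatenate([[0.0], z[:, 2]]))
        best_d = -np.inf
        best_h = 0.0
        labels = np.arange(m)
        for h in heights:
            lab = hierarchy.fcluster(z, t=h, criterion="distance")
            d = _partition_density(edges, lab)
            if d > best_d + 1e-12:
                best_d = d
                best_h = float(h)
                labels = lab
    # size filter + TM labels by decreasing size
    groups: dict[int, list[int]] = {}
    for i, lbl in enumerate(labels):
        groups.setdefault(int(lbl), []).append(i)
    kept = [idx for idx in groups.values() if len(idx) >= min_module_edges]
    kept.sort(key=lambda idx: (-len(idx), idx[0]))
    edge_modules: dict[tuple[str, str], str | None] = {e: None for e in edges}
    module_edges: dict[str, int] = {}
    module_nodes: dict[str, int] = {}
    for rank, idx in enumerate(kept, start=1):
        name = f"TM{rank:04d}"
        nodes = set()
        for i in idx:
            edge_modules[edges[i]] = name
            nodes.update(edges[i])
        module_edges[name] = len(idx)
        module_nodes[name] = len(nodes)
    return LinkCommunityPartition(
        edge_modules=edge_modules,
        module_edges=module_edges,
        module_nodes=module_nodes,
        density=_partition_density(edges, labels),
        cut_height=best_h,
    )


def module_gene_sets(partition: LinkCommunityPartition) -> dict[str, set[str]]:
    """Node set of each module: the union of its edges' endpoints."""
    out: dict[str, set[str]] = {}
    for (a, b), mod in partition.edge_modules.items():
        if mod is None:
            continue
        out.setdefault(mod, set()).update((a, b))
    return out
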