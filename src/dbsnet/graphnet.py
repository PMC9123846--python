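"""Region-level correlation structure and weighted graph centrality.

From the node atlas and the subject scans, a region-by-region Pearson
correlation matrix is estimated (per-subject correlations of region-mean
time courses, Fisher-z averaged across subjects and back-transformed). The
matrix is hierarchically clustered on Euclidean row distances, and turned
into an undirected weighted graph in which anticorrelated pairs carry no
edge. Betweenness and closeness centralities are computed on shortest paths
with edge length the reciprocal of the correlation weight, and reported
both raw and as standardised z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .overlap import NodeAtlas
from .seedmap import R_CLAMP, SubjectScan, extract_seed_timecourse

__all__ = [
    "CorrelationMatrix",
    "ClusterAssignment",
    "region_correlation_matrix",
    "hierarchical_cluster",
    "build_graph",
    "betweenness",
    "closeness",
    "zscore_centralities",
    "centrality_table",
    "write_edge_list",
]


@dataclass
class CorrelationMatrix:
    """Symmetric region-by-region Pearson correlation matrix."""

    labels: List[str]
    values: np.ndarray
    n_subjects: int
    flags: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(self.values)) > 1.0 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class ClusterAssignment:
    """Flat cut of the hierarchical tree into k clusters."""

    labels: List[str]
    cluster_id: Dict[str, int]
    k: int
    linkage_method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.labels,
             "cluster": [self.cluster_id[l] for l in self.labels]}
        )


def region_correlation_matrix(
    scans: List[SubjectScan], atlas: NodeAtlas
) -> CorrelationMatrix:
    """Cross-subject Pearson correlation between region-mean time courses.

    Per subject, each region's mean time course is extracted and all pairs
    correlated; per-subject correlations are Fisher-z transformed, averaged
    across subjects and back-transformed with tanh. A region whose time
    course has zero variance in some subject contributes r = 0 to all its
    pairs for that subject, counted in ``flags["zero_variance_pairs"]``.
    """
    if len(atlas) < 2:
        raise ValueError("need at least 2 regions")
    if len(scans) < 2:
        raise ValueError("need at least 2 subjects")
    labels = list(atlas.labels)
    n = len(labels)
    zsum = np.zeros((n, n))
    flagged = 0
    for scan in scans:
        tcs = np.stack(
            [extract_seed_timecourse(scan, _as_seed(atlas, name)) for name in labels]
        )
        sds = tcs.std(axis=1)
        degenerate = sds == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(tcs)
        if degenerate.any():
            r[degenerate, :] = 0.0
            r[:, degenerate] = 0.0
            flagged += int(degenerate.sum())
        np.fill_diagonal(r, 0.0)       # diagonal handled after averaging
        zsum += np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    values = np.tanh(zsum / len(scans))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(labels=labels, values=values, n_subjects=len(scans),
                             flags={"zero_variance_pairs": flagged})


def _as_seed(atlas: NodeAtlas, name: str):
    from .seedmap import SeedMask
    return SeedMask(name=name, mask=atlas.masks[name], affine=atlas.affine)


def hierarchical_cluster(
    matrix: CorrelationMatrix, k: int, method: str = "complete"
) -> ClusterAssignment:
    """Agglomerative clustering of matrix rows on Euclidean distances.

    The tree is cut into exactly k flat clusters; deterministic given the
    matrix. Complete linkage is the default.
    """
    n = len(matrix.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    if k == n:
        ids = {lab: i + 1 for i, lab in enumerate(matrix.labels)}
    elif k == 1:
        ids = {lab: 1 for lab in matrix.labels}
    else:
        dist = pdist(matrix.values, metric="euclidean")
        tree = linkage(dist, method=method)
        flat = fcluster(tree, t=k, criterion="maxclust")
        ids = {lab: int(c) for lab, c in zip(matrix.labels, flat)}
    return ClusterAssignment(labels=list(matrix.labels), cluster_id=ids, k=k,
                             linkage_method=method)


def build_graph(
    matrix: CorrelationMatrix,
    display_cutoff: float = 0.3,
    edge_length_convention: str = "inverse",
) -> nx.Graph:
    """Undirected weighted graph from the correlation matrix.

    Every pair with r > 0 becomes an edge of weight r; anticorrelated and
    uncorrelated pairs (r <= 0) carry no edge. Each edge also stores a
    shortest-path ``length`` (1/r by default, or 1 - r) and a
    ``below_cutoff`` flag for rendering; the display cutoff never removes
    edges from the computation.
    """
    if edge_length_convention not in ("inverse", "one_minus"):
        raise ValueError(f"unknown edge_length_convention {edge_length_convention!r}")
    g = nx.Graph(display_cutoff=display_cutoff)
    g.add_nodes_from(matrix.labels)
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(matrix.values[i, j])
            if r <= 0:
                continue
            length = 1.0 / r if edge_length_convention == "inverse" else 1.0 - r
            g.add_edge(matrix.labels[i], matrix.labels[j], weight=r,
                       length=length, below_cutoff=bool(r < display_cutoff))
    return g


def betweenness(graph: nx.Graph) -> Dict[str, float]:
    """Unnormalised weighted betweenness centrality.

    Shortest paths use the stored edge ``length``; a node's score is the
    number of node pairs whose shortest path runs through it, with
    fractional credit split over equal-length path multiplicities. On a
    disconnected graph pairs in different components contribute nothing
    (equivalent to per-component computation).
    """
    if graph.number_of_nodes() < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    return dict(nx.betweenness_centrality(graph, normalized=False, weight="length"))


def closeness(graph: nx.Graph) -> Dict[str, float]:
    """Weighted closeness centrality, per connected component.

    For a node in a component of size n_c, closeness is (n_c - 1) divided by
    the sum of shortest-path lengths (edge length as stored) to the other
    nodes of its component. Isolated nodes score 0.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("closeness needs at least 2 nodes")
    out: Dict[str, float] = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        out.update(nx.closeness_centrality(sub, distance="length"))
    return out


def zscore_centralities(values: Dict[str, float]) -> Dict[str, float]:
    """Standardise per-node values to mean 0, sample sd 1.

    A constant vector (sd = 0) maps to all zeros rather than NaN.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 nodes to standardise")
    nodes = list(values)
    x = np.array([values[n] for n in nodes], dtype=np.float64)
    sd = x.std(ddof=1)
    if sd == 0:
        return {n: 0.0 for n in nodes}
    z = (x - x.mean()) / sd
    return {n: float(v) for n, v in zip(nodes, z)}


def centrality_table(graph: nx.Graph) -> pd.DataFrame:
    """Betweenness and closeness, raw and z-scored, one row per node."""
    b = betweenness(graph)
    c = closeness(graph)
    bz = zscore_centralities(b)
    cz = zscore_centralities(c)
    nodes = list(graph.nodes)
    df = pd.DataFrame(
        {
            "region": nodes,
            "betweenness": [b[n] for n in nodes],
            "closeness": [c[n] for n in nodes],
            "betweenness_z": [bz[n] for n in nodes],
            "closeness_z": [cz[n] for n in nodes],
        }
    )
    df.attrs["connected"] = nx.is_connected(graph) if len(nodes) else True
    return df


def write_edge_list(graph: nx.Graph, path) -> None:
    """Tab-delimited edge list: node, node, weight."""
    rows = [
        {"source": u, "target": v, "weight": d["weight"]}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )
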