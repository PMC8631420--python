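"""Symptom co-occurrence networks and community structure.

Pairwise association between symptom indicators is measured by Spearman
rank correlation of the binary label columns; for binary data this equals
the Pearson (phi) coefficient, which is what is computed.  The thresholded
weighted graph is clustered with the Louvain modularity algorithm, and the
correlation matrix can be hierarchically clustered on distance 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .labels import N_CLASSES, SYMPTOMS, stack_labels

#: Default edge retention rule: correlation strictly above this value.
DEFAULT_EDGE_THRESHOLD = 0.09


def cooccurrence_matrix(
    labelsets: Sequence[Sequence[bool]],
) -> tuple[np.ndarray, tuple[str, ...]]:
    """12x12 symmetric correlation matrix over binary label columns.

    Returns ``(matrix, degenerate)``: entries involving a constant column
    (a class with only one outcome present) are NaN and those classes are
    listed in ``degenerate``.  The diagonal is 1 for well-defined classes.
    Spearman correlation of binary indicators equals the phi coefficient,
    computed here as the Pearson correlation of the 0/1 columns.
    """
    mat = stack_labels(labelsets).astype(float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 label sets")
    degenerate = tuple(
        SYMPTOMS[j] for j in range(N_CLASSES) if np.ptp(mat[:, j]) == 0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    for j, cls in enumerate(SYMPTOMS):
        if cls in degenerate:
            corr[j, :] = np.nan
            corr[:, j] = np.nan
        else:
            corr[j, j] = 1.0
    return corr, degenerate


def build_network(
    matrix: np.ndarray,
    prevalences: Sequence[float],
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
    names: Sequence[str] = SYMPTOMS,
) -> nx.Graph:
    """Weighted undirected graph keeping edges with correlation > threshold.

    Strict inequality; NaN (undefined) pairs never form edges.  Node
    attribute ``prevalence`` carries the symptom frequency for sizing.
    """
    matrix = np.asarray(matrix, dtype=float)
    k = matrix.shape[0]
    if matrix.shape != (k, k):
        raise ValueError("matrix must be square")
    finite = ~np.isnan(matrix)
    if not np.allclose(matrix[finite], matrix.T[finite]):
        raise ValueError("matrix must be symmetric")
    g = nx.Graph(edge_threshold=edge_threshold)
    for j, name in enumerate(names):
        g.add_node(name, prevalence=float(prevalences[j]))
    for i in range(k):
        for j in range(i + 1, k):
            w = matrix[i, j]
            if np.isfinite(w) and w > edge_threshold:
                g.add_edge(names[i], names[j], weight=float(w))
    return g


@dataclass(frozen=True)
class CommunityPartition:
    """Louvain partition with its modularity."""

    communities: tuple[frozenset, ...]
    modularity: float

    def community_of(self, node) -> int:
        for i, comm in enumerate(self.communities):
            if node in comm:
                return i
        raise KeyError(node)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node": node, "community_id": i}
            for i, comm in enumerate(self.communities)
            for node in sorted(comm)
        ]
        return pd.DataFrame(rows, columns=["node", "community_id"])


def detect_communities(graph: nx.Graph, seed: int = 0) -> CommunityPartition:
    """Weighted Louvain modularity maximisation.

    The partition's modularity is at least that of the trivial
    one-community partition (which is 0 for any graph with edges).
    An empty graph yields an empty partition.
    """
    if graph.number_of_nodes() == 0:
        return CommunityPartition(communities=(), modularity=0.0)
    if graph.number_of_edges() == 0:
        comms = tuple(frozenset({n}) for n in graph.nodes)
        return CommunityPartition(communities=comms, modularity=0.0)
    comms = louvain_communities(graph, weight="weight", seed=seed)
    q = modularity(graph, comms, weight="weight")
    return CommunityPartition(
        communities=tuple(frozenset(c) for c in comms), modularity=float(q)
    )


def cluster_symptoms(matrix: np.ndarray, method: str = "average") -> np.ndarray:
    """Hierarchical clustering of symptoms on distance 1 - r.

    Returns a scipy linkage matrix.  NaN entries (degenerate classes) are
    not allowed; drop those classes first.
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.isnan(matrix).any():
        raise ValueError("matrix contains undefined entries; drop degenerate classes")
    dist = 1.0 - matrix
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return linkage(squareform(dist, checks=False), method=method)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """TSV edge list: source, target, weight."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']:.6f}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
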