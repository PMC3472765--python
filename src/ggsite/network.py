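"""Interactome post-processing on confidence-weighted edge lists.

The input is a generic TSV edge list (node_a, node_b, confidence in
[0, 1]) such as an export from a protein-interaction database; querying
any such service is the user's job, not this module's.  Processing is
(1) an inclusive confidence threshold (>=, the usual database
convention, default 0.7) and (2) k-means clustering of the nodes
(default k = 5) in a spectral embedding of the confidence-weighted
adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WeightedEdgeList:
    """Undirected edges with confidences in [0, 1]; no self-loops.

    Node pairs are stored in canonical (sorted) order; duplicate pairs
    keep the maximum confidence.
    """

    edges: Tuple[Tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        canonical: Dict[Tuple[str, str], float] = {}
        for a, b, conf in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"confidence {conf} for edge ({a}, {b}) outside [0, 1]")
            key = (a, b) if a <= b else (b, a)
            canonical[key] = max(canonical.get(key, 0.0), conf)
        object.__setattr__(
            self,
            "edges",
            tuple(sorted((a, b, c) for (a, b), c in canonical.items())),
        )

    @property
    def nodes(self) -> List[str]:
        seen = sorted({n for a, b, _ in self.edges for n in (a, b)})
        return seen

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b, conf in self.edges:
            g.add_edge(a, b, weight=conf)
        return g


def read_edge_tsv(path) -> WeightedEdgeList:
    """Read a TSV with columns node_a, node_b, confidence."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"node_a": str, "node_b": str})
    required = {"node_a", "node_b", "confidence"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return WeightedEdgeList(
        tuple(
            (row.node_a, row.node_b, float(row.confidence))
            for row in df.itertuples(index=False)
        )
    )


def filter_edges(edges: WeightedEdgeList, min_confidence: float) -> WeightedEdgeList:
    """Retain edges with confidence >= min_confidence (inclusive)."""
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must lie in [0, 1], got {min_confidence}")
    return WeightedEdgeList(
        tuple(e for e in edges.edges if e[2] >= min_confidence)
    )


def filter_nodes_by_mean_confidence(
    edges: WeightedEdgeList, min_node_confidence: float
) -> WeightedEdgeList:
    """Optional per-node filter: drop nodes whose mean incident-edge
    confidence is below the threshold, with all their edges.

    This is one reading of a per-node confidence requirement; it is a
    documented interpretation, not a database-fidelity guarantee.
    """
    sums: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for a, b, conf in edges.edges:
        for n in (a, b):
            sums[n] = sums.get(n, 0.0) + conf
            counts[n] = counts.get(n, 0) + 1
    keep = {n for n in sums if sums[n] / counts[n] >= min_node_confidence}
    return WeightedEdgeList(
        tuple(e for e in edges.edges if e[0] in keep and e[1] in keep)
    )


def cluster_nodes(
    edges: WeightedEdgeList, k: int = 5, seed: int = 1
) -> Dict[str, int]:
    """Partition nodes into k clusters (ids 1..k), deterministically.

    The confidence-weighted adjacency is embedded spectrally into
    min(k, n-1) dimensions and the embedding is clustered with k-means
    at a fixed seed.  Disconnected components separate exactly in the
    embedding, so k-means on two cliques with k = 2 recovers them.
    """
    nodes = edges.nodes
    n = len(nodes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds node count {n}")
    if k == 1:
        return {node: 1 for node in nodes}
    if k == n:
        return {node: i + 1 for i, node in enumerate(nodes)}

    from scipy.sparse.csgraph import laplacian
    from sklearn.cluster import KMeans

    g = edges.to_graph()
    adjacency = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    lap = laplacian(adjacency, normed=True)
    eigvals, eigvecs = np.linalg.eigh(lap)
    dims = min(k, n - 1)
    embedding = eigvecs[:, :dims]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(embedding)
    # Relabel deterministically: cluster ids ordered by first member node.
    order: Dict[int, int] = {}
    for label in labels:
        if label not in order:
            order[label] = len(order) + 1
    return {node: order[label] for node, label in zip(nodes, labels)}
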