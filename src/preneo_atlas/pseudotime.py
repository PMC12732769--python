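"""One-dimensional progression ordering of preneoplastic-to-malignant cells.

A deliberately simple trajectory: ordering genes are chosen by expression
filters plus a cluster-wise Kruskal-Wallis test; cells are embedded in 2-D
PCA space; a minimum spanning tree connects cluster centroids; pseudotime
is the normalised geodesic distance from the root cluster along the tree,
with each cell projected onto its nearest tree edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, densify
from .errors import InputDataError
from .preprocess import _deterministic_pca


@dataclass
class OrderingGeneFilter:
    min_cells: int = 10
    min_mean: float = 0.1
    q_max: float = 0.01

    def __post_init__(self) -> None:
        if self.min_cells <= 0 or self.min_mean <= 0 or self.q_max <= 0:
            raise InputDataError("ordering-gene filter values must be positive")


def select_ordering_genes(normalized: np.ndarray, clusters: np.ndarray,
                          filt: OrderingGeneFilter | None = None) -> np.ndarray:
    """Genes expressed in >= min_cells cells with mean >= min_mean that vary
    across clusters (Kruskal-Wallis BH q < q_max)."""
    filt = filt or OrderingGeneFilter()
    X = densify(normalized)
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    if uniq.size < 2:
        raise InputDataError("cluster-wise ordering test needs >= 2 clusters")
    expressed = (X > 0).sum(axis=0) >= filt.min_cells
    abundant = X.mean(axis=0) >= filt.min_mean
    candidates = np.where(expressed & abundant)[0]
    if candidates.size == 0:
        raise InputDataError("no gene passes the expression filters; relax them")
    groups = [X[clusters == c] for c in uniq]
    pvals = np.ones(candidates.size)
    for i, j in enumerate(candidates):
        samples = [g[:, j] for g in groups]
        if all(np.ptp(s) == 0 for s in samples):
            continue
        with np.errstate(all="ignore"):
            try:
                pvals[i] = stats.kruskal(*samples).pvalue
            except ValueError:  # all values identical across groups
                pvals[i] = 1.0
    q = bh_adjust(pvals)
    selected = candidates[q < filt.q_max]
    if selected.size == 0:
        raise InputDataError("no ordering gene passes q_max; relax the filter")
    return selected


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray
    root_cluster: object
    mst_edges: list[tuple]
    embedding: np.ndarray
    centroids: pd.DataFrame


def order_cells(normalized: np.ndarray, ordering_genes, clusters: np.ndarray,
                root_weight: np.ndarray, n_pcs: int = 2) -> PseudotimeResult:
    """Order cells along a centroid MST in 2-D PCA space.

    ``root_weight`` is a per-cell indicator (or weight) of "origin" cells;
    the root is the cluster with the highest mean weight (intended usage:
    non-malignant PRE cells).  Pseudotime is geodesic distance from the
    root centroid to the cell's orthogonal projection on its nearest MST
    edge, normalised to [0, 1].
    """
    X = densify(normalized)[:, np.asarray(ordering_genes)]
    clusters = np.asarray(clusters)
    uniq = pd.unique(clusters)
    if uniq.size < 2:
        raise InputDataError("need at least 2 clusters to order")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    emb = _deterministic_pca((X - mu) / sd, n_pcs)

    cent = np.vstack([emb[clusters == c].mean(axis=0) for c in uniq])
    G = nx.Graph()
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            G.add_edge(i, j, weight=float(np.linalg.norm(cent[i] - cent[j])))
    T = nx.minimum_spanning_tree(G)
    if not nx.is_connected(T) or T.number_of_nodes() < len(uniq):
        raise InputDataError("centroid graph is disconnected")

    w = np.asarray(root_weight, dtype=float)
    root_scores = [w[clusters == c].mean() for c in uniq]
    root = int(np.argmax(root_scores))
    geo = nx.single_source_dijkstra_path_length(T, root)

    # project each cell onto its nearest tree edge segment
    edges = list(T.edges())
    best = np.full(emb.shape[0], np.inf)
    ptime = np.zeros(emb.shape[0])
    for u, v in edges:
        a, b = cent[u], cent[v]
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((emb - a) @ ab / denom, 0.0, 1.0) if denom > 0 else \
            np.zeros(emb.shape[0])
        proj = a + t[:, None] * ab
        dist = np.linalg.norm(emb - proj, axis=1)
        # geodesic coordinate of the projected point
        if geo[u] <= geo[v]:
            coord = geo[u] + t * np.sqrt(denom)
        else:
            coord = geo[v] + (1 - t) * np.sqrt(denom)
        closer = dist < best
        best[closer] = dist[closer]
        ptime[closer] = coord[closer]
    span = ptime.max() - ptime.min()
    if span > 0:
        ptime = (ptime - ptime.min()) / span
    centroids = pd.DataFrame(cent, index=uniq,
                             columns=[f"PC{i+1}" for i in range(cent.shape[1])])
    mst_edges = [(uniq[u], uniq[v]) for u, v in edges]
    return PseudotimeResult(pseudotime=ptime, root_cluster=uniq[root],
                            mst_edges=mst_edges, embedding=emb,
                            centroids=centroids)
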