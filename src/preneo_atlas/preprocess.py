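"""QC, normalisation, HVG selection, graph clustering and annotation.

The conventions follow common droplet scRNA-seq practice: cells are kept
when their detected-gene count lies inside an inclusive [min, max] band and
their mitochondrial fraction is strictly below the cap; normalisation is
log1p of library-size-scaled counts; highly variable genes are ranked by
standardised residual variance around a quadratic mean-variance trend;
clustering is modularity community detection on a shared-nearest-neighbour
graph built in PCA space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from ._utils import bh_adjust, densify
from .errors import ConfigurationError, EmptyResultWarning, InputDataError


@dataclass
class QcThresholds:
    min_genes: int = 200
    max_genes: int = 5000
    max_mito_fraction: float = 0.10
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0 < self.min_genes <= self.max_genes:
            raise ConfigurationError("need 0 < min_genes <= max_genes")
        if not 0 < self.max_mito_fraction <= 1:
            raise ConfigurationError("max_mito_fraction must lie in (0, 1]")


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    removed_low_genes: int
    removed_high_genes: int
    removed_mito: int


def qc_filter(counts, gene_names, thresholds: QcThresholds | None = None
              ) -> tuple[np.ndarray, QcReport]:
    """Cell quality control.

    Retains cells whose detected-gene count lies in the inclusive
    ``[min_genes, max_genes]`` band and whose mitochondrial count fraction
    is strictly below ``max_mito_fraction``.  Returns a boolean mask over
    cells and a per-criterion removal report.
    """
    thresholds = thresholds or QcThresholds()
    X = counts
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise InputDataError("empty count matrix")
    if sp.issparse(X):
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        detected = (X > 0).sum(axis=1)
        totals = X.sum(axis=1)
    mito_idx = [i for i, g in enumerate(gene_names)
                if str(g).startswith(thresholds.mito_gene_prefix)]
    if mito_idx:
        sub = X[:, mito_idx]
        mito = np.asarray(sub.sum(axis=1)).ravel() if sp.issparse(sub) \
            else np.asarray(sub).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    else:
        mito_frac = np.zeros(X.shape[0])

    low = detected < thresholds.min_genes
    high = detected > thresholds.max_genes
    mito_bad = mito_frac >= thresholds.max_mito_fraction
    keep = ~(low | high | mito_bad)
    report = QcReport(
        n_input=X.shape[0], n_retained=int(keep.sum()),
        removed_low_genes=int(low.sum()), removed_high_genes=int(high.sum()),
        removed_mito=int(mito_bad.sum()))
    if report.n_retained == 0:
        warnings.warn("QC removed every cell", EmptyResultWarning)
    return keep, report


def lognormalize(counts, scale: float = 1e4, cell_names=None) -> np.ndarray:
    """x = ln(1 + scale * c / T) with T the cell's total count."""
    X = densify(counts)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.where(totals <= 0)[0]
        name = cell_names[bad[0]] if cell_names is not None else f"index {bad[0]}"
        raise InputDataError(f"cell {name} has zero total count")
    return np.log1p(scale * X / totals[:, None])


def select_hvgs(counts, n: int = 2000, gene_names=None) -> np.ndarray:
    """Top-``n`` highly variable genes by standardised residual variance.

    A quadratic trend of log10(variance) on log10(mean) is fit over raw
    counts; counts are standardised with the trend-expected SD, clipped at
    sqrt(n_cells), and genes are ranked by the variance of the clipped
    standardised values.  Ties break by gene identifier so the order is
    deterministic.
    """
    X = densify(counts)
    n_cells, n_genes = X.shape
    if gene_names is None:
        gene_names = np.arange(n_genes)
    gene_names = np.asarray(gene_names)
    if n > n_genes:
        raise ConfigurationError(f"requested {n} HVGs from {n_genes} genes")
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    usable = (mean > 0) & (var > 0)
    std_var = np.zeros(n_genes)
    if usable.sum() >= 3:
        lm, lv = np.log10(mean[usable]), np.log10(var[usable])
        coef = np.polyfit(lm, lv, deg=2)
        exp_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[usable])))
        Z = (X[:, usable] - mean[usable]) / exp_sd
        Z = np.clip(Z, -np.sqrt(n_cells), np.sqrt(n_cells))
        std_var[usable] = Z.var(axis=0, ddof=1)
    order = np.lexsort((gene_names, -std_var))
    return order[:n]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    resolution: float
    n_pcs: int
    seed: int
    stage_composition: pd.DataFrame | None = field(default=None)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _deterministic_pca(X: np.ndarray, n_pcs: int) -> np.ndarray:
    """PCA via eigendecomposition of the smaller Gram matrix.

    Deterministic and invariant to row/column order (up to component sign,
    fixed by making each loading's largest-magnitude entry positive).
    """
    Xc = X - X.mean(axis=0)
    n, g = Xc.shape
    n_pcs = min(n_pcs, n - 1, g)
    if g <= n:
        C = Xc.T @ Xc
        w, V = np.linalg.eigh(C)
        idx = np.argsort(w)[::-1][:n_pcs]
        V = V[:, idx]
        for j in range(V.shape[1]):
            k = np.argmax(np.abs(V[:, j]))
            if V[k, j] < 0:
                V[:, j] = -V[:, j]
        return Xc @ V
    G = Xc @ Xc.T
    w, U = np.linalg.eigh(G)
    idx = np.argsort(w)[::-1][:n_pcs]
    w, U = w[idx], U[:, idx]
    comp = U * np.sqrt(np.maximum(w, 1e-12))
    for j in range(comp.shape[1]):
        k = np.argmax(np.abs(comp[:, j]))
        if comp[k, j] < 0:
            comp[:, j] = -comp[:, j]
    return comp


def snn_graph(embedding: np.ndarray, k_neighbors: int = 20,
              prune: float = 1 / 15) -> sp.csr_matrix:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = embedding.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    A = nn.kneighbors_graph(embedding, mode="connectivity")  # includes self
    shared = A @ A.T
    shared = shared.tocoo()
    union = 2 * (k + 1) - shared.data
    jac = shared.data / union
    keep = jac >= prune
    W = sp.coo_matrix((jac[keep], (shared.row[keep], shared.col[keep])),
                      shape=(n, n)).tocsr()
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def cluster_cells(normalized: np.ndarray, hvgs, n_pcs: int = 30,
                  resolution: float = 0.9, k_neighbors: int = 20,
                  seed: int = 0, batch: np.ndarray | None = None,
                  stages: np.ndarray | None = None) -> ClusterAssignment:
    """PCA -> kNN -> SNN-Jaccard -> modularity community detection.

    ``batch``, when given, triggers per-batch per-gene mean centering of the
    scaled HVG matrix before PCA (a linear stand-in for iterative batch
    integration; flagged in the returned assignment via the seed record).
    """
    X = densify(normalized)
    n = X.shape[0]
    if n < k_neighbors + 1:
        raise InputDataError(
            f"need at least {k_neighbors + 1} cells, got {n}")
    H = X[:, np.asarray(hvgs)] if hvgs is not None else X
    mu, sd = H.mean(axis=0), H.std(axis=0)
    sd[sd == 0] = 1.0
    H = np.clip((H - mu) / sd, -10, 10)
    if batch is not None:
        batch = np.asarray(batch)
        for b in np.unique(batch):
            m = batch == b
            H[m] -= H[m].mean(axis=0)
    if n <= n_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {n - 1}")
        n_pcs = n - 1
    emb = _deterministic_pca(H, n_pcs)
    W = snn_graph(emb, k_neighbors=k_neighbors)
    sources, targets = W.nonzero()
    upper = sources < targets
    g = igraph.Graph(n=n, edges=list(zip(sources[upper], targets[upper])),
                     edge_attrs={"weight": np.asarray(W[sources[upper],
                                                        targets[upper]]).ravel()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution,
        seed=int(seed), n_iterations=2)
    labels = np.asarray(part.membership)
    comp = None
    if stages is not None:
        tab = pd.crosstab(pd.Series(labels, name="cluster"),
                          pd.Series(np.asarray(stages), name="stage"))
        comp = tab.div(tab.sum(axis=1), axis=0)
    return ClusterAssignment(labels=labels, resolution=resolution,
                             n_pcs=n_pcs, seed=seed, stage_composition=comp)


def annotate_clusters(normalized: np.ndarray, labels: np.ndarray,
                      marker_sets: dict[str, list[str]], gene_names
                      ) -> pd.DataFrame:
    """Assign each cluster the marker set with the highest mean z-score.

    Ties resolve to the lexicographically smallest type label and the
    cluster is flagged low-confidence.  Marker sets with no matching genes
    are skipped with a warning.
    """
    X = densify(normalized)
    gene_index = {g: i for i, g in enumerate(gene_names)}
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    types, score_cols = [], []
    for t in sorted(marker_sets):
        idx = [gene_index[g] for g in marker_sets[t] if g in gene_index]
        if not idx:
            warnings.warn(f"marker set {t!r} has no matching genes; skipped")
            continue
        types.append(t)
        score_cols.append(Z[:, idx].mean(axis=1))
    if not types:
        raise InputDataError("no marker set matched any gene")
    S = np.column_stack(score_cols)
    rows = []
    for c in np.unique(labels):
        sc = S[labels == c].mean(axis=0)
        best = sc.max()
        winners = [types[j] for j in range(len(types))
                   if np.isclose(sc[j], best, atol=1e-12)]
        rows.append({"cluster": c, "cell_type": sorted(winners)[0],
                     "score": best, "low_confidence": len(winners) > 1})
    return pd.DataFrame(rows).set_index("cluster")


def wilcoxon_de(normalized: np.ndarray, group_a: np.ndarray,
                group_b: np.ndarray, logfc_min: float = 0.5,
                min_pct: float = 0.5, alpha: float = 0.05,
                pseudocount: float = 1e-9,
                p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression with pre-filters.

    Genes enter the test only when the higher-expressing group's expressing
    fraction reaches ``min_pct`` and |log2FC| (on de-logged normalised
    means) exceeds ``logfc_min``.  Small groups (both <= 8 cells) use the
    exact permutation distribution of the rank-sum statistic; larger groups
    use the tie-corrected normal approximation.

    ``p_adjust`` sets the multiple-testing universe: ``"bonferroni"``
    (default) corrects over every gene in the matrix, matching the
    convention of the standard single-cell toolchain and guarding against
    the selection bias the fold-change pre-filter introduces;
    ``"bh_all"`` applies BH with untested genes entered at p = 1;
    ``"bh_tested"`` applies BH over the tested genes only.
    """
    X = densify(normalized)
    A = X[np.asarray(group_a, dtype=np.intp)]
    B = X[np.asarray(group_b, dtype=np.intp)]
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise InputDataError("empty group in differential expression")
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise InputDataError("both groups need at least 3 cells")
    mean_a = np.expm1(A).mean(axis=0)
    mean_b = np.expm1(B).mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    pct_1 = (A > 0).mean(axis=0)
    pct_2 = (B > 0).mean(axis=0)
    tested = (np.maximum(pct_1, pct_2) >= min_pct) & (np.abs(log2fc) > logfc_min)

    pvals = np.full(X.shape[1], np.nan)
    idx = np.where(tested)[0]
    if idx.size:
        if A.shape[0] <= 8 and B.shape[0] <= 8:
            for j in idx:
                pvals[j] = _exact_ranksum_p(A[:, j], B[:, j])
        else:
            with np.errstate(all="ignore"):
                res = stats.mannwhitneyu(A[:, idx], B[:, idx], axis=0,
                                         alternative="two-sided",
                                         method="asymptotic")
            p = np.atleast_1d(res.pvalue)
            # constant genes yield NaN; they carry no evidence
            pvals[idx] = np.where(np.isnan(p), 1.0, p)
    p_adj = np.full(X.shape[1], np.nan)
    if idx.size:
        if p_adjust == "bonferroni":
            p_adj[idx] = np.minimum(pvals[idx] * X.shape[1], 1.0)
        elif p_adjust == "bh_all":
            filled = np.where(np.isnan(pvals), 1.0, pvals)
            p_adj[idx] = bh_adjust(filled)[idx]
        elif p_adjust == "bh_tested":
            p_adj[idx] = bh_adjust(pvals[idx])
        else:
            raise ConfigurationError(f"unknown p_adjust mode {p_adjust!r}")
    table = pd.DataFrame({
        "log2fc": log2fc, "pct_1": pct_1, "pct_2": pct_2,
        "p": pvals, "p_adj": p_adj, "tested": tested,
    })
    table["significant"] = tested & (table["p_adj"] < alpha)
    return table


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration of group splits."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    res = stats.permutation_test(
        (a, b), lambda x, y, axis=-1: _ranksum_stat(x, y, axis),
        permutation_type="independent", alternative="two-sided",
        n_resamples=np.inf, vectorized=True)
    return float(res.pvalue)


def _ranksum_stat(x, y, axis):
    z = np.concatenate([x, y], axis=axis)
    ranks = stats.rankdata(z, axis=axis)
    nx = x.shape[axis]
    return np.take(ranks, np.arange(nx), axis=axis).sum(axis=axis)
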