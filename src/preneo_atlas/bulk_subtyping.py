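"""Bulk-cohort batch adjustment, consensus subtyping and subtype DE.

Consensus clustering follows the resampling scheme of Monti et al.:
repeated subsampling of samples, average-linkage hierarchical clustering
with a 1 - Pearson distance, and a consensus matrix of co-clustering
frequencies among co-sampled pairs.  The number of clusters is chosen by
minimising the proportion of ambiguous clustering (PAC) over (0.1, 0.9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._utils import bh_adjust
from .errors import InputDataError

PAC_BOUNDS = (0.1, 0.9)


def batch_adjust(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Per-batch location/scale standardisation of a samples x genes matrix.

    Per gene and batch: subtract the batch mean, rescale the batch SD to
    the pooled within-batch SD, re-add the grand mean.  Zero-variance
    genes pass through; single-sample batches are left unadjusted with a
    warning.
    """
    batches = pd.Series(np.asarray(batches), index=matrix.index)
    X = matrix.to_numpy(dtype=float).copy()
    grand = X.mean(axis=0)
    groups = {b: np.where((batches == b).to_numpy())[0]
              for b in batches.unique()}
    small = [b for b, idx in groups.items() if idx.size < 2]
    if small:
        warnings.warn(f"single-sample batches left unadjusted: {small}")
    usable = {b: idx for b, idx in groups.items() if idx.size >= 2}
    if not usable:
        raise InputDataError("every batch has fewer than 2 samples")
    within_var = np.zeros_like(grand)
    n_tot = 0
    for idx in usable.values():
        within_var += X[idx].var(axis=0, ddof=0) * idx.size
        n_tot += idx.size
    pooled_sd = np.sqrt(within_var / n_tot)
    out = X.copy()
    for idx in usable.values():
        mu = X[idx].mean(axis=0)
        sd = X[idx].std(axis=0, ddof=0)
        scale = np.where(sd > 0, pooled_sd / np.where(sd > 0, sd, 1.0), 1.0)
        out[idx] = (X[idx] - mu) * scale + grand
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class ConsensusResult:
    consensus: dict                      # k -> consensus matrix (n x n)
    pac: dict                            # k -> PAC score
    k: int
    assignments: pd.Series               # sample -> subtype label "S1"...
    n_resample: int
    subsample_fraction: float
    sample_names: list = field(default_factory=list)


def _pac(C: np.ndarray, lower: float, upper: float) -> float:
    iu = np.triu_indices_from(C, k=1)
    vals = C[iu]
    return float(((vals > lower) & (vals < upper)).mean())


def consensus_cluster(matrix: pd.DataFrame, genes, k_range=range(2, 9),
                      n_resample: int = 450, frac: float = 0.8,
                      seed: int = 0) -> ConsensusResult:
    """Monti consensus clustering of samples on the given genes."""
    genes = [g for g in genes if g in matrix.columns]
    if not genes:
        raise InputDataError("none of the requested genes are present")
    X = matrix[genes].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant genes")
        X = X[:, keep]
    # median-center genes so the correlation distance reflects deviation
    # structure rather than the shared expression-level profile
    X = X - np.median(X, axis=0, keepdims=True)
    n = X.shape[0]
    k_range = list(k_range)
    if n < max(k_range):
        raise InputDataError(f"need >= {max(k_range)} samples")
    if n < 2 * max(k_range):
        warnings.warn("fewer than 2*k samples; large-k consensus is degenerate")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(frac * n))

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sample = np.zeros((n, n))
    for _ in range(n_resample):
        idx = rng.choice(n, size=m, replace=False)
        co_sample[np.ix_(idx, idx)] += 1
        D = 1.0 - np.corrcoef(X[idx])
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        for k in k_range:
            labels = fcluster(Z, t=k, criterion="maxclust")
            eq = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(idx, idx)] += eq

    consensus, pac = {}, {}
    with np.errstate(invalid="ignore"):
        for k in k_range:
            C = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
            np.fill_diagonal(C, 1.0)
            C = (C + C.T) / 2
            consensus[k] = C
            pac[k] = _pac(C, *PAC_BOUNDS)
    best_k = min(k_range, key=lambda k: (pac[k], k))

    Zc = linkage(squareform(1.0 - consensus[best_k], checks=False),
                 method="average")
    raw = fcluster(Zc, t=best_k, criterion="maxclust")
    # stable naming: subtypes numbered by first appearance in sample order
    order = {}
    for lab in raw:
        if lab not in order:
            order[lab] = f"S{len(order) + 1}"
    labels = pd.Series([order[lab] for lab in raw], index=matrix.index,
                       name="subtype")
    return ConsensusResult(consensus=consensus, pac=pac, k=best_k,
                           assignments=labels, n_resample=n_resample,
                           subsample_fraction=frac,
                           sample_names=list(matrix.index))


def subtype_composition(subtypes: pd.Series, stages) -> pd.DataFrame:
    """Row-normalised stage fractions per subtype."""
    stages = pd.Series(np.asarray(stages), index=subtypes.index)
    tab = pd.crosstab(subtypes, stages)
    return tab.div(tab.sum(axis=1), axis=0)


def subtype_de(adjusted: pd.DataFrame, subtypes: pd.Series,
               alpha: float = 0.05, logfc_min: float = 0.5,
               min_samples: int = 3) -> dict[str, pd.DataFrame]:
    """One-vs-rest Welch t-tests per subtype on log2 expression.

    log2FC is the difference of group means (the matrix is log2 scale);
    significance requires BH-adjusted p < ``alpha`` and |log2FC| >
    ``logfc_min``.  Subtypes under ``min_samples`` samples are skipped.
    """
    X = adjusted.to_numpy(dtype=float)
    out = {}
    for sub in sorted(subtypes.unique()):
        mask = (subtypes == sub).to_numpy()
        if mask.sum() < min_samples or (~mask).sum() < min_samples:
            warnings.warn(f"subtype {sub} has too few samples; contrast skipped")
            continue
        a, b = X[mask], X[~mask]
        log2fc = a.mean(axis=0) - b.mean(axis=0)
        with np.errstate(all="ignore"):
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        tab = pd.DataFrame({"log2fc": log2fc, "t": t, "p": p,
                            "p_adj": bh_adjust(p)}, index=adjusted.columns)
        tab["significant"] = (tab["p_adj"] < alpha) & \
            (tab["log2fc"].abs() > logfc_min)
        out[sub] = tab
    return out
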