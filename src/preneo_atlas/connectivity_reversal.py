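"""Weighted-KS connectivity scoring and signature-reversal ranking.

Query signatures (top up- and down-regulated genes of a disease group) are
matched against a reference of perturbagen differential z-score profiles.
For each profile, weighted Kolmogorov-Smirnov enrichment scores of the up
and down sets combine into the weighted two-sample connectivity score
WTCS = (ES_up - ES_down) / 2 when the two scores disagree in sign, else 0.
WTCS is normalised within same-sign scores of a reference annotation group
(NCS), averaged over a perturbagen's replicate profiles, and tested with a
random-gene-set permutation p-value.  Reversal candidates are perturbagens
with mean NCS < 0, ranked by p then mean NCS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputDataError


@dataclass
class QuerySignature:
    name: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    excluded: bool = False
    reason: str = ""


def build_signature(table: pd.DataFrame, name: str, alpha: float = 0.05,
                    logfc_min: float = 0.15, top_n: int = 200,
                    min_genes: int = 5) -> QuerySignature:
    """Build an up/down query signature from a differential table.

    Genes pass with BH-adjusted p < ``alpha`` and |log2FC| strictly above
    ``logfc_min``; each direction keeps its ``top_n`` genes by |log2FC|.
    Signatures with fewer than ``min_genes`` genes on either side are
    excluded (recorded, not raised).
    """
    ok = (table["p_adj"] < alpha) & (table["log2fc"].abs() > logfc_min)
    up = table.loc[ok & (table["log2fc"] > 0), "log2fc"] \
        .sort_values(ascending=False).head(top_n)
    down = table.loc[ok & (table["log2fc"] < 0), "log2fc"] \
        .sort_values(ascending=True).head(top_n)
    sig = QuerySignature(name=name, up=list(up.index), down=list(down.index))
    if len(sig.up) < min_genes or len(sig.down) < min_genes:
        sig.excluded = True
        sig.reason = (f"{len(sig.up)} up / {len(sig.down)} down genes "
                      f"after filtering; need >= {min_genes} each")
    return sig


def _es_from_positions(pos: np.ndarray, ranked_weights: np.ndarray,
                       n_total: int) -> np.ndarray:
    """Weighted-KS enrichment scores from hit positions.

    ``pos`` is (batch, n_hits) of 0-based positions into the ranked list,
    sorted ascending per row; ``ranked_weights`` are |score|^w in rank
    order.  Returns one signed ES per row.
    """
    batch, n_hits = pos.shape
    w = ranked_weights[pos]
    tot = w.sum(axis=1, keepdims=True)
    flat = tot[:, 0] <= 0
    if np.any(flat):              # zero-weight sets: unweighted KS fallback
        w[flat] = 1.0
        tot[flat] = n_hits
    cw = np.cumsum(w, axis=1) / tot
    miss = 1.0 / (n_total - n_hits) if n_total > n_hits else 0.0
    offset = (pos - np.arange(n_hits)[None, :]) * miss
    after = cw - offset                       # running sum just after a hit
    before = np.concatenate(
        [np.zeros((batch, 1)), cw[:, :-1]], axis=1) - offset
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    # extremum of largest magnitude; magnitude ties (within float noise)
    # resolve to the extremum reached earlier in the ranked walk, the
    # sequential definition of the running-sum score
    tol = 1e-12
    rows = np.arange(batch)
    i_hi = np.argmax(after >= hi[:, None] - tol, axis=1)
    i_lo = np.argmax(before <= lo[:, None] + tol, axis=1)
    pos_hi = pos[rows, i_hi]           # walk position of the maximum
    pos_lo = pos[rows, i_lo] - 1       # minimum occurs just before a hit
    take_hi = np.abs(hi) > np.abs(lo) + tol
    tie = np.abs(np.abs(hi) - np.abs(lo)) <= tol
    take_hi |= tie & (pos_hi <= pos_lo)
    return np.where(take_hi, hi, lo)


def weighted_es(profile: pd.Series, gene_set, weight_exp: float = 1.0) -> float:
    """Weighted-KS enrichment score of ``gene_set`` in a ranked profile.

    The profile is ranked by score descending (ties broken by gene name
    for determinism); hits advance the running sum by |score|^weight_exp
    normalised over hits, misses retreat by 1/(N - n_set); ES is the
    extremum of largest magnitude.
    """
    genes = list(gene_set)
    if len(genes) == 0:
        raise InputDataError("empty gene set")
    missing = [g for g in genes if g not in profile.index]
    if missing:
        raise InputDataError(f"genes absent from profile: {missing[:5]}")
    ranked = profile.reset_index()
    ranked.columns = ["gene", "score"]
    ranked = ranked.sort_values(["score", "gene"], ascending=[False, True],
                                kind="stable").reset_index(drop=True)
    pos_of = {g: i for i, g in enumerate(ranked["gene"])}
    pos = np.sort(np.array([pos_of[g] for g in genes]))[None, :]
    weights = np.abs(ranked["score"].to_numpy()) ** weight_exp
    return float(_es_from_positions(pos, weights, len(profile))[0])


def wtcs(profile: pd.Series, signature: QuerySignature,
         weight_exp: float = 1.0, min_genes: int = 5) -> dict:
    """Weighted two-sample connectivity score of one profile vs a signature.

    Signature genes absent from the profile are dropped; when a side falls
    below ``min_genes`` the score is marked missing.
    """
    if signature.excluded:
        raise InputDataError(f"signature {signature.name} was excluded")
    up = [g for g in signature.up if g in profile.index]
    down = [g for g in signature.down if g in profile.index]
    if len(up) < min_genes or len(down) < min_genes:
        return {"es_up": np.nan, "es_down": np.nan, "wtcs": np.nan,
                "missing": True}
    es_up = weighted_es(profile, up, weight_exp)
    es_down = weighted_es(profile, down, weight_exp)
    if np.sign(es_up) != np.sign(es_down):
        score = (es_up - es_down) / 2.0
    else:
        score = 0.0
    return {"es_up": es_up, "es_down": es_down, "wtcs": score,
            "missing": False}


def ncs_and_p(reference: pd.DataFrame, annotation: pd.DataFrame,
              signature: QuerySignature, weight_exp: float = 1.0,
              n_perm: int = 1000, seed: int = 0,
              min_genes: int = 5) -> pd.DataFrame:
    """Score every reference profile and rank perturbagens by reversal.

    ``reference`` is genes x profiles; ``annotation`` (indexed by profile)
    must carry ``perturbagen`` and ``pert_class`` columns.  Per profile the
    permutation p compares |WTCS| against ``n_perm`` random disjoint
    up/down gene sets of matched sizes drawn from the profile's genes (the
    same random sets are reused across profiles, a common-random-numbers
    scheme).  Returns a per-perturbagen table with mean NCS (the reversal
    'similarity'), the minimum profile p-value, the retained flag
    (mean NCS < 0) and the rank among retained perturbagens.
    """
    if signature.excluded:
        raise InputDataError(f"signature {signature.name} was excluded")
    profiles = list(reference.columns)
    missing_ann = [p for p in profiles if p not in annotation.index]
    if missing_ann:
        raise InputDataError(f"profiles without annotation: {missing_ann[:5]}")
    up = [g for g in signature.up if g in reference.index]
    down = [g for g in signature.down if g in reference.index]
    if len(up) < min_genes or len(down) < min_genes:
        raise InputDataError("signature too small after matching to reference")
    n_genes = reference.shape[0]
    n_up, n_down = len(up), len(down)

    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n_genes))
    subset = np.argpartition(keys, n_up + n_down - 1, axis=1)[:, :n_up + n_down]
    perm_up = np.sort(subset[:, :n_up], axis=1)
    perm_down = np.sort(subset[:, n_up:], axis=1)

    gene_pos_template = pd.Index(reference.index)
    up_idx = gene_pos_template.get_indexer(up)
    down_idx = gene_pos_template.get_indexer(down)

    scores = []
    Z = reference.to_numpy(dtype=float)
    gene_names = reference.index.to_numpy()
    for j, prof in enumerate(profiles):
        col = Z[:, j]
        order = np.lexsort((gene_names, -col))
        ranked_w = np.abs(col[order]) ** weight_exp
        rank_of = np.empty(n_genes, dtype=int)
        rank_of[order] = np.arange(n_genes)
        es_up = float(_es_from_positions(
            np.sort(rank_of[up_idx])[None, :], ranked_w, n_genes)[0])
        es_down = float(_es_from_positions(
            np.sort(rank_of[down_idx])[None, :], ranked_w, n_genes)[0])
        obs = (es_up - es_down) / 2.0 if np.sign(es_up) != np.sign(es_down) else 0.0
        pes_up = _es_from_positions(perm_up, ranked_w, n_genes)
        pes_down = _es_from_positions(perm_down, ranked_w, n_genes)
        pw = np.where(np.sign(pes_up) != np.sign(pes_down),
                      (pes_up - pes_down) / 2.0, 0.0)
        p = (1.0 + np.sum(np.abs(pw) >= np.abs(obs))) / (n_perm + 1.0)
        scores.append({"profile": prof, "es_up": es_up, "es_down": es_down,
                       "wtcs": obs, "p": p})
    tab = pd.DataFrame(scores).set_index("profile")
    tab["perturbagen"] = annotation.loc[tab.index, "perturbagen"]
    tab["pert_class"] = annotation.loc[tab.index, "pert_class"]

    # NCS: normalise within (annotation group, sign of WTCS)
    tab["ncs"] = np.nan
    for cls, sub in tab.groupby("pert_class"):
        for sgn in (-1.0, 1.0):
            m = np.sign(sub["wtcs"]) == sgn
            if m.any():
                denom = sub.loc[m, "wtcs"].abs().mean()
                tab.loc[sub.index[m], "ncs"] = sub.loc[m, "wtcs"] / denom
    zero = tab["wtcs"] == 0
    tab.loc[zero, "ncs"] = 0.0
    if tab["ncs"].isna().any():
        warnings.warn("profiles with undefined NCS excluded from means")

    per_pert = tab.groupby("perturbagen").agg(
        mean_ncs=("ncs", "mean"), p=("p", "min"),
        n_profiles=("ncs", "size")).reset_index()
    per_pert["retained"] = per_pert["mean_ncs"] < 0
    per_pert = per_pert.sort_values(["p", "mean_ncs", "perturbagen"],
                                    kind="stable").reset_index(drop=True)
    per_pert["rank"] = np.nan
    per_pert.loc[per_pert["retained"], "rank"] = \
        np.arange(1, int(per_pert["retained"].sum()) + 1)
    per_pert.attrs["signature"] = signature.name
    per_pert.attrs["profile_scores"] = tab
    return per_pert
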