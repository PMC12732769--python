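"""Ligand-receptor crosstalk scoring between cell groups.

Communication probability follows a mass-action Hill form: with L the
sender group's ligand summary expression and R the receiver group's
receptor summary expression (25 %-truncated means of log-normalised
values), P = L*R / (Kh + L*R), saturating at 1 with half-saturation at
L*R = Kh.  Significance comes from a label-permutation test with an
add-one rule so p-values never reach zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputDataError

MIN_GROUP_CELLS = 10
TRIM = 0.25


@dataclass(frozen=True)
class LrPair:
    ligand: str
    receptor: str
    pathway: str = ""

    @property
    def name(self) -> str:
        return f"{self.ligand}-{self.receptor}"


def communication_probability(L: float, R: float, kh: float = 0.5) -> float:
    """P = L*R / (Kh + L*R); monotone in L and R, P(0, .) = 0."""
    if kh <= 0:
        raise InputDataError("Kh must be positive")
    lr = L * R
    return float(lr / (kh + lr))


def _summary(values: np.ndarray) -> float:
    """25 %-truncated mean; robust summary of group expression."""
    return float(stats.trim_mean(values, TRIM))


def score_pair(normalized: np.ndarray, sender: np.ndarray,
               receiver: np.ndarray, pair: LrPair, gene_index: dict,
               kh: float = 0.5) -> dict | None:
    """Score one ligand-receptor pair for one (sender, receiver) duo.

    Returns None when either gene is absent from the expression universe
    (the pair is skipped).  Raises when a group is under-populated.
    """
    if pair.ligand not in gene_index or pair.receptor not in gene_index:
        return None
    sender = np.asarray(sender)
    receiver = np.asarray(receiver)
    if len(sender) < MIN_GROUP_CELLS or len(receiver) < MIN_GROUP_CELLS:
        raise InputDataError(
            f"groups need >= {MIN_GROUP_CELLS} cells to score {pair.name}")
    L = _summary(normalized[sender, gene_index[pair.ligand]])
    R = _summary(normalized[receiver, gene_index[pair.receptor]])
    return {"ligand": pair.ligand, "receptor": pair.receptor,
            "pair": pair.name, "pathway": pair.pathway,
            "L": L, "R": R, "P": communication_probability(L, R, kh)}


def score_pairs(normalized: np.ndarray, sender: np.ndarray,
                receiver: np.ndarray, pairs: list[LrPair], gene_names,
                kh: float = 0.5, n_perm: int = 100,
                seed: int = 0) -> pd.DataFrame:
    """Score a table of LR pairs with a joint permutation test.

    The permutation shuffles the sender/receiver split of the pooled cells
    ``n_perm`` times; p = (1 + #{P_perm >= P_obs}) / (n_perm + 1).
    """
    gene_index = {g: i for i, g in enumerate(gene_names)}
    rows, lig_cols, rec_cols = [], [], []
    for pair in pairs:
        row = score_pair(normalized, sender, receiver, pair, gene_index, kh)
        if row is None:
            continue
        rows.append(row)
        lig_cols.append(gene_index[pair.ligand])
        rec_cols.append(gene_index[pair.receptor])
    if not rows:
        return pd.DataFrame(columns=["ligand", "receptor", "pair", "pathway",
                                     "L", "R", "P", "p_perm"])
    obs = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([np.asarray(sender), np.asarray(receiver)])
    ns = len(sender)
    lig_mat = normalized[np.ix_(pooled, lig_cols)]
    rec_mat = normalized[np.ix_(pooled, rec_cols)]
    exceed = np.zeros(len(rows))
    p_obs = obs["P"].to_numpy()
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        Lp = stats.trim_mean(lig_mat[perm[:ns]], TRIM, axis=0)
        Rp = stats.trim_mean(rec_mat[perm[ns:]], TRIM, axis=0)
        Pp = (Lp * Rp) / (kh + Lp * Rp)
        exceed += Pp >= p_obs
    obs["p_perm"] = (1.0 + exceed) / (n_perm + 1.0)
    return obs


def stage_aggregate(scores: pd.DataFrame, alpha: float = 0.05) -> float:
    """Total communication strength: sum of P over significant pairs."""
    if scores.empty:
        return 0.0
    sig = scores[scores["p_perm"] < alpha]
    return float(sig["P"].sum())


def group_heat_table(scores_by_duo: dict[tuple, pd.DataFrame],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-(sender, receiver) significant-strength sums (heatmap input)."""
    rows = [{"sender": s, "receiver": r, "strength": stage_aggregate(t, alpha)}
            for (s, r), t in scores_by_duo.items()]
    return pd.DataFrame(rows)


def top_pairs(scores: pd.DataFrame, n: int = 80) -> pd.DataFrame:
    """Rank pairs by (p_perm asc, P desc, name asc); return the top ``n``.

    When fewer than ``n`` pairs exist the full table is returned with a
    ``truncated`` attribute flag.
    """
    ranked = scores.sort_values(["p_perm", "P", "pair"],
                                ascending=[True, False, True],
                                kind="stable").reset_index(drop=True)
    out = ranked.head(n).copy()
    out.attrs["truncated"] = len(ranked) > n
    out.attrs["requested"] = n
    return out


def shared_sets(stage_sets: dict[str, set]) -> pd.DataFrame:
    """Intersection counts of significant pair identities across stages.

    One row per non-empty stage combination (UpSet-style exclusive
    intersections) plus per-stage totals.
    """
    from itertools import combinations

    stages = list(stage_sets)
    rows = []
    for k in range(len(stages), 0, -1):
        for combo in combinations(stages, k):
            inside = set.intersection(*(stage_sets[s] for s in combo))
            outside = set().union(*(stage_sets[s] for s in stages
                                    if s not in combo)) if k < len(stages) else set()
            exclusive = inside - outside
            rows.append({"stages": "&".join(combo), "n_stages": k,
                         "intersection": len(inside),
                         "exclusive": len(exclusive)})
    return pd.DataFrame(rows)
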