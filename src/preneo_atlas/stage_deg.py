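"""Stage-pair differential expression and persistent-dysregulation calls.

A gene is called persistently dysregulated when it moves in the same
direction in all three stage contrasts (PRE/NOR, PDA/PRE, PDA/NOR), where
each contrast's gene set is the union of significant per-cell-type calls.
Over-representation of gene sets uses the upper-tail hypergeometric test
with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust
from .errors import InputDataError
from .preprocess import wilcoxon_de

CONTRASTS = (("PRE", "Normal", "PRE/NOR"),
             ("PDAC", "PRE", "PDA/PRE"),
             ("PDAC", "Normal", "PDA/NOR"))


@dataclass
class StageContrast:
    label: str
    cell_type: str
    table: pd.DataFrame | None
    available: bool = True
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)


def stage_contrasts(normalized: np.ndarray, stages: np.ndarray,
                    cell_types: np.ndarray, cell_type: str, gene_names,
                    min_cells: int = 3, **de_kwargs) -> list[StageContrast]:
    """Run the three stage-pair Wilcoxon contrasts within one cell type.

    Contrasts with a missing or under-populated stage are returned with
    ``available=False`` rather than silently empty.
    """
    stages = np.asarray(stages)
    cell_types = np.asarray(cell_types)
    gene_names = np.asarray(gene_names)
    out = []
    mask_t = cell_types == cell_type
    for hi, lo, label in CONTRASTS:
        a = np.where(mask_t & (stages == hi))[0]
        b = np.where(mask_t & (stages == lo))[0]
        if len(a) < min_cells or len(b) < min_cells:
            out.append(StageContrast(label, cell_type, None, available=False))
            continue
        tab = wilcoxon_de(normalized, a, b, **de_kwargs)
        tab.index = gene_names
        sig = tab["significant"]
        up = set(tab.index[sig & (tab["log2fc"] > 0)])
        down = set(tab.index[sig & (tab["log2fc"] < 0)])
        out.append(StageContrast(label, cell_type, tab, True, up, down))
    return out


@dataclass
class PersistentGeneCall:
    gene: str
    direction: str
    support: dict


def call_persistent_genes(contrasts: list[StageContrast]
                          ) -> tuple[list[PersistentGeneCall], list[str]]:
    """Intersect per-contrast union DEG sets over all cell types.

    ``contrasts`` is the flat list over all cell types.  Persistent-up is
    the intersection of the three contrasts' up-set unions, likewise for
    down.  Genes appearing in both intersections (through different cell
    types) are dropped and returned as conflicts.
    """
    labels = {label for _, _, label in CONTRASTS}
    by_label: dict[str, list[StageContrast]] = {lb: [] for lb in labels}
    for c in contrasts:
        if c.label in by_label:
            by_label[c.label].append(c)
    for lb, lst in by_label.items():
        if not lst or not any(c.available for c in lst):
            raise InputDataError(f"contrast {lb} unavailable for every cell type")

    up_unions, down_unions = {}, {}
    for lb, lst in by_label.items():
        up_unions[lb] = set().union(*(c.up for c in lst if c.available))
        down_unions[lb] = set().union(*(c.down for c in lst if c.available))
    persist_up = set.intersection(*up_unions.values())
    persist_down = set.intersection(*down_unions.values())
    conflicts = sorted(persist_up & persist_down)
    persist_up -= set(conflicts)
    persist_down -= set(conflicts)

    def support(gene: str, direction: str) -> dict:
        return {c.label: c.cell_type for c in contrasts if c.available
                and gene in (c.up if direction == "up" else c.down)}

    calls = [PersistentGeneCall(g, "up", support(g, "up"))
             for g in sorted(persist_up)]
    calls += [PersistentGeneCall(g, "down", support(g, "down"))
              for g in sorted(persist_down)]
    return calls, conflicts


def overlap_summary(sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise |A ∩ B| counts and |A ∩ B| / |A| fractions for ordered pairs."""
    rows = []
    for a_name, a in sets.items():
        for b_name, b in sets.items():
            if a_name == b_name:
                continue
            inter = len(a & b)
            rows.append({"set_a": a_name, "set_b": b_name, "n_a": len(a),
                         "n_b": len(b), "overlap": inter,
                         "fraction_of_a": inter / len(a) if a else np.nan})
    return pd.DataFrame(rows)


def enrich(query: set, gene_sets: dict[str, set], universe: set,
           q_max: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation with BH correction.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set ∩ universe|,
    n=|query|).  Rows with q < ``q_max`` are flagged significant.
    """
    if not universe:
        raise InputDataError("empty universe")
    if not set(query) <= set(universe):
        raise InputDataError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, gset in gene_sets.items():
        K = len(gset & universe)
        k = len(gset & set(query))
        # upper tail P(X >= k) = survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"gene_set": name, "k": k, "K": K, "n": n, "N": N, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < q_max
    return table.sort_values("p", kind="stable").reset_index(drop=True)
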