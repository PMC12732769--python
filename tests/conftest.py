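"""Shared fixtures: the default synthetic cohort and per-seed summaries.

Heavy objects are session-scoped so the unit suite and the acceptance
suite reuse one computation.  Multi-seed fixtures keep only summaries to
bound memory.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import balanced_accuracy_score

from preneo_atlas import (CohortConfig, abundance_table, call_malignant,
                          cluster_cells, designate_malignant_pre,
                          generate_single_cell, infer_cnv, lognormalize,
                          order_cells, select_hvgs, select_ordering_genes,
                          stage_network)
from preneo_atlas.synthetic_cohort import IMMUNE_TYPES

SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def cohort1():
    """Default synthetic cohort at seed 1 with normalised expression."""
    adata, truth = generate_single_cell(CohortConfig(seed=1))
    norm = lognormalize(adata.X, cell_names=adata.obs_names)
    hvgs = select_hvgs(adata.X, n=2000, gene_names=adata.var_names)
    return {"adata": adata, "truth": truth, "norm": norm, "hvgs": hvgs,
            "stages": adata.obs["stage"].to_numpy(),
            "cell_types": adata.obs["cell_type"].to_numpy()}


def _seed_summary(seed: int) -> dict:
    adata, truth = generate_single_cell(CohortConfig(seed=seed))
    norm = lognormalize(adata.X)
    hvgs = select_hvgs(adata.X, n=2000, gene_names=adata.var_names)
    stages = adata.obs["stage"].to_numpy()
    ctype = adata.obs["cell_type"].to_numpy()
    batch = adata.obs["batch"].to_numpy()
    tm = truth.cells["malignancy"].to_numpy()

    profiles = infer_cnv(adata.X, adata.var[["chromosome", "start"]],
                         ctype == "B", adata.var_names)
    malignant = call_malignant(profiles, stages)
    pdac = stages == "PDAC"
    true_mal = tm == "malignant"
    bal_acc = balanced_accuracy_score(true_mal[pdac], malignant[pdac])

    epi = np.isin(ctype, ["Ductal", "Acinar"])
    sub = cluster_cells(norm[epi], hvgs, seed=seed, batch=batch[epi])
    designations = designate_malignant_pre(norm[epi], sub.labels, stages[epi],
                                           malignant[epi], hvgs=hvgs)
    truth_malpre_frac = {
        d.cluster: float((tm[epi][sub.labels == d.cluster] == "malignant_pre").mean())
        for d in designations}

    # lineage-wise trajectories: PRE cells of the lineage plus malignant
    # cells, ordered from the non-malignant PRE root
    malpre_clusters = {d.cluster for d in designations
                       if d.designation == "malignant_pre"}
    epi_idx = np.where(epi)[0]
    sub_of = np.full(adata.n_obs, -1)
    sub_of[epi_idx] = sub.labels
    rho = {}
    for lineage in ("Ductal", "Acinar"):
        mask = np.zeros(adata.n_obs, dtype=bool)
        mask[(ctype == lineage) & (stages == "PRE") & epi] = True
        mask[malignant] = True
        prog = np.where(mask)[0]
        ordering = select_ordering_genes(norm[prog], sub_of[prog])
        root_w = ((stages[prog] == "PRE")
                  & ~np.isin(sub_of[prog], list(malpre_clusters))).astype(float)
        ptime = order_cells(norm[prog], ordering, sub_of[prog], root_w)
        prog_label = np.where(tm[prog] == "malignant", 2,
                              np.where(tm[prog] == "malignant_pre", 1, 0))
        rho[lineage] = float(spearmanr(ptime.pseudotime, prog_label).statistic)

    imm = np.isin(ctype, IMMUNE_TYPES)
    abun = abundance_table(adata.obs["sample"].to_numpy()[imm], stages[imm],
                           ctype[imm], immune_types=set(IMMUNE_TYPES))
    edges = {st: stage_network(abun, st) for st in ("Normal", "PDAC")}

    return {"seed": seed, "balanced_accuracy": float(bal_acc),
            "designations": designations,
            "truth_malpre_frac": truth_malpre_frac,
            "pseudotime_rho": rho, "network_edges": edges}


@pytest.fixture(scope="session")
def seed_summaries():
    """CNV, designation, pseudotime and network summaries for seeds 1-5."""
    return [_seed_summary(s) for s in SEEDS]
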