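"""End-to-end pipeline driver with a seeded, hash-recorded run manifest.

Stages run in order: synthetic cohort -> QC/normalise/cluster/annotate ->
stage DE + persistent genes + enrichment -> CNV malignancy + malignant-PRE
designation -> pseudotime -> immune abundance networks -> ligand-receptor
crosstalk -> bulk consensus subtyping -> signature-reversal screen.  Every
stage's tabular outputs are written under the run directory and digested
into the manifest, so a rerun with the same configuration can be verified
bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import STAGES
from .abundance_network import abundance_table, edges_to_frame, stage_network
from .bulk_subtyping import (batch_adjust, consensus_cluster,
                             subtype_composition, subtype_de)
from .cnv_malignancy import call_malignant, designate_malignant_pre, infer_cnv
from .connectivity_reversal import build_signature, ncs_and_p
from .crosstalk import LrPair, score_pairs, stage_aggregate, top_pairs
from .errors import ConfigurationError
from .preprocess import (QcThresholds, annotate_clusters, cluster_cells,
                         lognormalize, qc_filter, select_hvgs, wilcoxon_de)
from .pseudotime import OrderingGeneFilter, order_cells, select_ordering_genes
from .stage_deg import call_persistent_genes, enrich, stage_contrasts
from .synthetic_cohort import (IMMUNE_TYPES, CohortConfig,
                               generate_bulk, generate_perturbagen_reference,
                               generate_single_cell)

#: full configuration schema with the pipeline's default thresholds
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "synthetic": {},                    # CohortConfig overrides
    "qc": {"min_genes": 200, "max_genes": 5000, "max_mito_fraction": 0.10,
           "mito_gene_prefix": "MT-"},
    "normalize": {"scale": 1e4},
    "hvg": {"n": 2000},
    "cluster": {"n_pcs": 30, "resolution": 0.9, "k_neighbors": 20,
                "batch_center": True},
    "de": {"logfc_min": 0.5, "min_pct": 0.5, "alpha": 0.05},
    "enrich": {"q_max": 0.05},
    "cnv": {"window": 51, "expr_min": 0.1, "k_sd": 3.0,
            "reference_type": "B", "r_min": 0.75, "pre_min": 0.5,
            "subcluster_resolution": 0.9},
    "ordering": {"min_cells": 10, "min_mean": 0.1, "q_max": 0.01},
    "network": {"min_samples": 5},
    "crosstalk": {"kh": 0.5, "n_perm": 100, "alpha": 0.05, "top_n": 80,
                  "sender": "Macrophage", "receiver": "Ductal"},
    "consensus": {"k_min": 2, "k_max": 8, "n_resample": 450, "frac": 0.8},
    "subtype_de": {"alpha": 0.05, "logfc_min": 0.5},
    "signature": {"alpha": 0.05, "logfc_min": 0.15, "top_n": 200,
                  "min_genes": 5},
    "reversal": {"n_perm": 1000, "weight_exp": 1.0},
}


def load_config(source=None) -> dict:
    """Merge a user config (dict or YAML path) onto the defaults.

    Unknown keys raise before any compute.
    """
    if source is None:
        user = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for key, val in user.items():
        if key not in cfg:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigurationError(f"section {key!r} must be a mapping")
            if key != "synthetic":
                unknown = set(val) - set(cfg[key])
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys in {key!r}: {sorted(unknown)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages_completed: list
    output_digests: dict
    thresholds: dict
    runtime_s: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_obj(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()


def run_pipeline(config=None, outdir="pipeline_run") -> RunManifest:
    """Execute the full pipeline on a synthetic cohort; return the manifest."""
    t0 = time.time()
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    completed: list[str] = []
    digests: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path)
        digests[name] = _digest_file(path)

    # --- synthetic cohort -------------------------------------------------
    syn_kwargs = dict(cfg["synthetic"])
    syn_kwargs.setdefault("seed", seed)
    ccfg = CohortConfig(**syn_kwargs)
    adata, truth = generate_single_cell(ccfg)
    digests["counts"] = _digest_obj(
        (adata.X.indptr.tobytes(), adata.X.indices.tobytes(),
         adata.X.data.tobytes()))
    completed.append("synthetic")

    # --- preprocess -------------------------------------------------------
    keep, qc_report = qc_filter(adata.X, adata.var_names,
                                QcThresholds(**cfg["qc"]))
    adata = adata[keep].copy()
    norm = lognormalize(adata.X, scale=cfg["normalize"]["scale"],
                        cell_names=adata.obs_names)
    hvgs = select_hvgs(adata.X, n=min(cfg["hvg"]["n"], adata.n_vars),
                       gene_names=adata.var_names)
    batch = adata.obs["batch"].to_numpy() if cfg["cluster"]["batch_center"] \
        else None
    assign = cluster_cells(norm, hvgs, n_pcs=cfg["cluster"]["n_pcs"],
                           resolution=cfg["cluster"]["resolution"],
                           k_neighbors=cfg["cluster"]["k_neighbors"],
                           seed=seed, batch=batch,
                           stages=adata.obs["stage"].to_numpy())
    ann = annotate_clusters(norm, assign.labels, adata.uns["marker_sets"],
                            adata.var_names)
    cell_type = ann.loc[assign.labels, "cell_type"].to_numpy()
    obs_out = adata.obs.copy()
    obs_out["cluster"] = assign.labels
    obs_out["annotated_type"] = cell_type
    save(obs_out, "cells.csv")
    completed.append("preprocess")

    # --- stage DE and persistent genes ------------------------------------
    stages = adata.obs["stage"].to_numpy()
    contrasts = []
    for ctype in sorted(set(cell_type)):
        contrasts += stage_contrasts(norm, stages, cell_type, ctype,
                                     adata.var_names, **cfg["de"])
    calls, conflicts = call_persistent_genes(contrasts)
    persist = pd.DataFrame([{"gene": c.gene, "direction": c.direction}
                            for c in calls]).set_index("gene") \
        if calls else pd.DataFrame(columns=["direction"])
    save(persist, "persistent_genes.csv")
    universe = set(adata.var_names)
    up_genes = {c.gene for c in calls if c.direction == "up"}
    if up_genes:
        sets = {k: set(v) for k, v in adata.uns["pathway_sets"].items()}
        save(enrich(up_genes, sets, universe, cfg["enrich"]["q_max"]),
             "enrichment_up.csv")
    completed.append("stage_deg")

    # --- CNV malignancy ---------------------------------------------------
    gene_map = adata.var[["chromosome", "start"]]
    ref_mask = cell_type == cfg["cnv"]["reference_type"]
    profiles = infer_cnv(adata.X, gene_map, ref_mask, adata.var_names,
                         window=cfg["cnv"]["window"],
                         expr_min=cfg["cnv"]["expr_min"])
    malignant = call_malignant(profiles, stages, k_sd=cfg["cnv"]["k_sd"])
    epi = np.isin(cell_type, ["Ductal", "Acinar"])
    sub_assign = cluster_cells(
        norm[epi], hvgs, n_pcs=cfg["cluster"]["n_pcs"],
        resolution=cfg["cnv"]["subcluster_resolution"],
        k_neighbors=cfg["cluster"]["k_neighbors"], seed=seed,
        batch=batch[epi] if batch is not None else None)
    designations = designate_malignant_pre(
        norm[epi], sub_assign.labels, stages[epi], malignant[epi],
        hvgs=hvgs, r_min=cfg["cnv"]["r_min"], pre_min=cfg["cnv"]["pre_min"])
    cnv_out = pd.DataFrame({"burden": profiles.burden,
                            "malignant": malignant}, index=adata.obs_names)
    save(cnv_out, "cnv_calls.csv")
    save(pd.DataFrame([d.__dict__ for d in designations]).set_index("cluster"),
         "malignant_pre_designations.csv")
    completed.append("cnv_malignancy")

    # --- pseudotime (per lineage) -----------------------------------------
    mal_pre_clusters = {d.cluster for d in designations
                       if d.designation == "malignant_pre"}
    epi_idx = np.where(epi)[0]
    sub_of = np.full(adata.n_obs, -1)
    sub_of[epi_idx] = sub_assign.labels
    ptime_frames = []
    for lineage in ("Ductal", "Acinar"):
        mask = np.zeros(adata.n_obs, dtype=bool)
        mask[(cell_type == lineage) & (stages == "PRE") & epi] = True
        mask[malignant] = True
        prog = np.where(mask)[0]
        try:
            ordering = select_ordering_genes(
                norm[prog], sub_of[prog], OrderingGeneFilter(**cfg["ordering"]))
            root_w = ((stages[prog] == "PRE")
                      & ~np.isin(sub_of[prog],
                                 list(mal_pre_clusters))).astype(float)
            ptime = order_cells(norm[prog], ordering, sub_of[prog], root_w)
            ptime_frames.append(pd.DataFrame(
                {"lineage": lineage, "pseudotime": ptime.pseudotime,
                 "cluster": sub_of[prog]}, index=adata.obs_names[prog]))
        except Exception as exc:         # degenerate subclustering is possible
            digests[f"pseudotime_error_{lineage}"] = str(exc)
    if ptime_frames:
        save(pd.concat(ptime_frames), "pseudotime.csv")
        completed.append("pseudotime")

    # --- immune abundance networks ----------------------------------------
    immune_mask = np.isin(cell_type, list(IMMUNE_TYPES))
    abun = abundance_table(adata.obs["sample"].to_numpy()[immune_mask],
                           stages[immune_mask], cell_type[immune_mask],
                           immune_types=set(IMMUNE_TYPES))
    save(abun, "abundance.csv")
    all_edges = []
    for stage in STAGES:
        edges = stage_network(abun, stage,
                              min_samples=cfg["network"]["min_samples"])
        df = edges_to_frame(edges)
        df.insert(0, "stage", stage)
        all_edges.append(df)
    save(pd.concat(all_edges, ignore_index=True), "network_edges.csv")
    completed.append("abundance_network")

    # --- crosstalk ---------------------------------------------------------
    lr_tab = adata.uns["lr_pairs"]
    pairs = [LrPair(r.ligand, r.receptor, r.pathway)
             for r in lr_tab.itertuples()]
    ct_cfg = cfg["crosstalk"]
    stage_scores = {}
    for stage in STAGES:
        sm = (cell_type == ct_cfg["sender"]) & (stages == stage)
        rm = (cell_type == ct_cfg["receiver"]) & (stages == stage)
        if sm.sum() < 10 or rm.sum() < 10:
            stage_scores[stage] = pd.DataFrame(
                columns=["pair", "P", "p_perm", "pathway"])
            continue
        stage_scores[stage] = score_pairs(
            norm, np.where(sm)[0], np.where(rm)[0], pairs, adata.var_names,
            kh=ct_cfg["kh"], n_perm=ct_cfg["n_perm"], seed=seed)
    agg = pd.DataFrame({
        "stage": list(STAGES),
        "total_strength": [stage_aggregate(stage_scores[s], ct_cfg["alpha"])
                           for s in STAGES]}).set_index("stage")
    save(agg, "crosstalk_aggregate.csv")
    scored = pd.concat([s.assign(stage=st) for st, s in stage_scores.items()
                        if not s.empty], ignore_index=True)
    save(scored, "crosstalk_scores.csv")
    for stage in STAGES:
        if not stage_scores[stage].empty:
            save(top_pairs(stage_scores[stage], ct_cfg["top_n"]),
                 f"crosstalk_top_{stage}.csv")
    completed.append("crosstalk")

    # --- bulk subtyping ----------------------------------------------------
    bulk, bulk_meta, bulk_truth = generate_bulk(ccfg)
    adj = batch_adjust(bulk, bulk_meta["batch"])
    lr_genes = sorted(set(lr_tab["ligand"]) | set(lr_tab["receptor"]))
    cons = consensus_cluster(adj, lr_genes,
                             k_range=range(cfg["consensus"]["k_min"],
                                           cfg["consensus"]["k_max"] + 1),
                             n_resample=cfg["consensus"]["n_resample"],
                             frac=cfg["consensus"]["frac"], seed=seed)
    save(cons.assignments.to_frame(), "bulk_subtypes.csv")
    save(subtype_composition(cons.assignments, bulk_meta["stage"]),
         "subtype_composition.csv")
    sde = subtype_de(adj, cons.assignments, **cfg["subtype_de"])
    for sub, tab in sde.items():
        save(tab, f"subtype_de_{sub}.csv")
    completed.append("bulk_subtyping")

    # --- reversal screen ---------------------------------------------------
    sig_cfg = cfg["signature"]
    groups = {}
    for sub in sorted(cons.assignments.unique()):
        for stage in STAGES:
            m = ((cons.assignments == sub)
                 & (bulk_meta["stage"] == stage)).to_numpy()
            if m.sum() >= 3:
                groups[f"{sub}-{stage}"] = m
    signatures, score_vectors = {}, {}
    for gname, m in groups.items():
        tab = subtype_de(adj, pd.Series(np.where(m, gname, "rest"),
                                        index=adj.index),
                         alpha=sig_cfg["alpha"],
                         logfc_min=sig_cfg["logfc_min"]).get(gname)
        if tab is None:
            continue
        sig = build_signature(tab, gname, alpha=sig_cfg["alpha"],
                              logfc_min=sig_cfg["logfc_min"],
                              top_n=sig_cfg["top_n"],
                              min_genes=sig_cfg["min_genes"])
        if not sig.excluded:
            signatures[gname] = sig
            score_vectors[gname] = tab["log2fc"]
    if signatures:
        target = sorted(signatures)[0]
        reference, annotation, ref_truth = generate_perturbagen_reference(
            ccfg, score_vectors, target=target)
        result = ncs_and_p(reference, annotation, signatures[target],
                           weight_exp=cfg["reversal"]["weight_exp"],
                           n_perm=cfg["reversal"]["n_perm"], seed=seed)
        save(result.set_index("perturbagen"), "reversal_ranking.csv")
    completed.append("reversal")

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        seed=seed, stages_completed=completed, output_digests=digests,
        thresholds={k: v for k, v in cfg.items() if isinstance(v, dict)},
        runtime_s=round(time.time() - t0, 2))
    manifest.to_json(outdir / "manifest.json")
    return manifest
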