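"""Synthetic three-stage pancreatic cohort generator.

Emulates the study conditions of a Normal → preneoplastic (PRE) → PDAC
single-cell atlas together with matched bulk cohorts and a perturbagen
z-score reference, with planted structure that the downstream pipeline is
expected to recover:

* stage-dependent cell-type composition (immune collapse in PRE, ductal and
  acinar expansion, macrophage expansion across stages),
* persistently up-/down-regulated genes with monotone fold steps per stage
  transition,
* copy-number segments carried by malignant PDAC ductal cells, attenuated
  in malignant preneoplastic cells whose expression is a mixture of the
  malignant and the normal-PRE program,
* a planted anti-correlated immune-subtype pair across samples,
* stage-increasing ligand-receptor channels between macrophages and the
  ductal lineage,
* four bulk molecular subtypes realised on ligand-receptor genes with
  additive batch structure, and
* planted signature-reversing perturbagens in the reference.

Counts are negative binomial around per-(type, stage, malignancy) mean
programs defined in log space; copy number acts multiplicatively on the
negative-binomial means (a dosage model). All randomness flows from one
root seed through named substreams so each component can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import STAGES, substream
from .errors import ConfigurationError

IMMUNE_TYPES = ("B", "Plasma", "T_CD4", "T_CD8", "NKT", "Macrophage")
EPITHELIAL_TYPES = ("Ductal", "Acinar")
OTHER_TYPES = ("Endothelial", "Stromal")
CELL_TYPES = IMMUNE_TYPES + EPITHELIAL_TYPES + OTHER_TYPES

#: immune compartment share of all cells per stage (the atlas' printed trend)
_IMMUNE_SHARE = {"Normal": 0.695, "PRE": 0.157, "PDAC": 0.543}


def _default_stage_composition() -> dict[str, dict[str, float]]:
    """Per-stage cell-type proportions.

    The immune/epithelial split follows the atlas' reported stage dynamics
    (immune 69.5 / 15.7 / 54.3 %, ductal+acinar 19.2 / 68.6 / 21.4 %,
    macrophages 0.6 / 19.3 / 20.9 % of immune cells); the finer splits are
    this generator's choices.
    """
    immune = {
        # fractions of the immune compartment
        "Normal": {"B": 0.25, "Plasma": 0.05, "T_CD4": 0.20, "T_CD8": 0.20,
                   "NKT": 0.294, "Macrophage": 0.006},
        "PRE": {"B": 0.20, "Plasma": 0.10, "T_CD4": 0.15, "T_CD8": 0.15,
                "NKT": 0.207, "Macrophage": 0.193},
        "PDAC": {"B": 0.15, "Plasma": 0.16, "T_CD4": 0.12, "T_CD8": 0.15,
                 "NKT": 0.211, "Macrophage": 0.209},
    }
    non_immune = {
        "Normal": {"Ductal": 0.096, "Acinar": 0.096,
                   "Endothelial": 0.057, "Stromal": 0.056},
        "PRE": {"Ductal": 0.186, "Acinar": 0.500,
                "Endothelial": 0.080, "Stromal": 0.077},
        "PDAC": {"Ductal": 0.190, "Acinar": 0.024,
                 "Endothelial": 0.120, "Stromal": 0.123},
    }
    comp = {}
    for stage in STAGES:
        share = _IMMUNE_SHARE[stage]
        vec = {t: share * f for t, f in immune[stage].items()}
        vec.update(non_immune[stage])
        comp[stage] = vec
    return comp


@dataclass
class CohortConfig:
    """All tunables of the synthetic cohort; defaults are the study conditions."""

    n_genes: int = 2000
    n_chromosomes: int = 10
    cells_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"Normal": 1500, "PRE": 1500, "PDAC": 1500})
    samples_per_stage: int = 30
    stage_composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_stage_composition)
    marker_fold: float = 8.0
    n_markers_per_type: int = 10
    persistent_up_genes: int = 40
    persistent_down_genes: int = 40
    persistent_step: float = 2.0          # fold change per stage transition
    program_genes: int = 150              # malignant expression program size
    program_fold: float = 3.0
    cnv_segments: Sequence[tuple[int, str, float]] = field(
        default_factory=lambda: [(0, "gain", 2.0), (2, "loss", 0.5),
                                 (4, "loss", 0.5)])
    pre_malignant_attenuation: float = 0.5  # CNV log-multiplier shrink
    mixing_alpha: float = 0.6             # malignant-program weight in mal-PRE
    malignant_fraction: float = 0.8       # of PDAC ductal cells
    malignant_pre_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"Ductal": 0.18, "Acinar": 0.15})
    macrophage_share_sd: float = 0.7      # per-sample lognormal jitter (log sd)
    immune_jitter_sd: float = 0.15
    other_jitter_sd: float = 0.10
    nb_dispersion: float = 0.3
    base_mean: float = 1.5
    base_log_sd: float = 0.1
    cell_size_log_sd: float = 0.2
    n_mito_genes: int = 20
    mito_mean_fold: float = 6.0
    n_batches: int = 4
    sc_batch_log_sd: float = 0.1
    # ligand-receptor channels
    n_lr_pairs: int = 30
    n_lr_active: int = 5                  # stage-increasing channels
    n_lr_constant: int = 5                # stage-constant active channels
    lr_base_mean: float = 0.05
    lr_active_fold: float = 10.0
    lr_stage_step: float = 2.0
    # bulk cohort
    bulk_samples_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"Normal": 77, "PRE": 72, "PDAC": 84})
    n_bulk_batches: int = 4
    bulk_base_mean: float = 6.0
    bulk_subtype_shift: float = 2.0       # log2 units on a subtype's LR block
    bulk_mixing_max: float = 0.55         # minor-archetype loading ceiling
    bulk_stage_shift: float = 1.0         # log2 units per stage transition
    bulk_batch_sd: float = 0.5
    bulk_noise_sd: float = 0.9
    # perturbagen reference
    n_perturbagens: int = 100
    n_reversers: int = 5
    n_replicates: int = 3
    reverser_correlation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise ConfigurationError("gene and chromosome counts must be positive")
        if any(n <= 0 for n in self.cells_per_stage.values()):
            raise ConfigurationError("cells_per_stage entries must be positive")
        for stage, vec in self.stage_composition.items():
            total = sum(vec.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"stage {stage!r} composition sums to {total}, expected 1")
            if any(p < 0 for p in vec.values()):
                raise ConfigurationError("composition proportions must be >= 0")
        for chrom, kind, mult in self.cnv_segments:
            if not (0 <= chrom < self.n_chromosomes):
                raise ConfigurationError(f"CNV chromosome {chrom} out of range")
            if kind not in ("gain", "loss") or mult <= 0:
                raise ConfigurationError("CNV segments need kind gain/loss and multiplier > 0")
        if not 0 <= self.mixing_alpha <= 1:
            raise ConfigurationError("mixing_alpha must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        # planted blocks must fit on the chromosomes free of CNV segments
        per_chr = self.n_genes // self.n_chromosomes
        cnv_chroms = {c for c, _, _ in self.cnv_segments}
        free = (self.n_chromosomes - len(cnv_chroms)) * per_chr
        needed = (self.persistent_up_genes + self.persistent_down_genes
                  + len(CELL_TYPES) * self.n_markers_per_type
                  + self.program_genes + 2 * self.n_lr_pairs + self.n_mito_genes)
        if needed > free:
            raise ConfigurationError(
                f"planted structure needs {needed} genes but only {free} are "
                "available outside CNV segments")
        if self.n_lr_active + self.n_lr_constant > self.n_lr_pairs:
            raise ConfigurationError("active + constant LR channels exceed n_lr_pairs")
        if self.n_reversers > self.n_perturbagens:
            raise ConfigurationError("more reversers than perturbagens")


@dataclass
class GroundTruth:
    """Planted labels for every generated unit; the acceptance oracle."""

    cells: pd.DataFrame | None = None          # barcode -> type/stage/malignancy
    genes: pd.DataFrame | None = None          # gene -> persistent direction
    bulk_samples: pd.DataFrame | None = None   # sample -> subtype/stage/batch
    perturbagens: pd.DataFrame | None = None   # perturbagen -> reverser flag
    lr_activity: pd.DataFrame | None = None    # pair x stage activity level


# ---------------------------------------------------------------------------
# gene universe


@dataclass
class _GeneLayout:
    names: list[str]
    chrom: np.ndarray
    start: np.ndarray
    persistent_up: np.ndarray
    persistent_down: np.ndarray
    markers: dict[str, np.ndarray]
    program: np.ndarray
    ligands: np.ndarray
    receptors: np.ndarray
    mito: np.ndarray
    cnv_mult: np.ndarray                  # full multiplier per gene (malignant)


def _gene_layout(cfg: CohortConfig) -> _GeneLayout:
    per_chr = cfg.n_genes // cfg.n_chromosomes
    chrom = np.minimum(np.arange(cfg.n_genes) // per_chr, cfg.n_chromosomes - 1)
    start = np.empty(cfg.n_genes, dtype=int)
    for c in range(cfg.n_chromosomes):
        idx = np.where(chrom == c)[0]
        start[idx] = np.arange(1, idx.size + 1)   # unit-spaced, 1-based

    cnv_chroms = {c for c, _, _ in cfg.cnv_segments}
    free = np.where(~np.isin(chrom, list(cnv_chroms)))[0]
    # scatter planted genes across the genome (fixed layout permutation):
    # isolated positions keep marker/program structure from mimicking a
    # copy-number segment under positional smoothing
    free = np.random.default_rng(20240915).permutation(free)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        block = free[cursor:cursor + n]
        cursor += n
        return block

    persistent_up = take(cfg.persistent_up_genes)
    persistent_down = take(cfg.persistent_down_genes)
    markers = {t: take(cfg.n_markers_per_type) for t in CELL_TYPES}
    program = take(cfg.program_genes)
    ligands = take(cfg.n_lr_pairs)
    receptors = take(cfg.n_lr_pairs)
    mito = take(cfg.n_mito_genes)

    names = [f"G{i:04d}" for i in range(cfg.n_genes)]
    for j, g in enumerate(mito):
        names[g] = f"MT-{j:02d}"
    cnv_mult = np.ones(cfg.n_genes)
    for c, _, mult in cfg.cnv_segments:
        cnv_mult[chrom == c] = mult
    return _GeneLayout(names, chrom, start, persistent_up, persistent_down,
                       markers, program, ligands, receptors, mito, cnv_mult)


def _log_means(cfg: CohortConfig, lay: _GeneLayout,
               rng: np.random.Generator) -> dict:
    """Per-(type, stage, malignancy) log-mean expression programs."""
    base = np.log(cfg.base_mean) + rng.normal(0.0, cfg.base_log_sd, cfg.n_genes)
    base[lay.persistent_up] += np.log(2.0)     # elevated baseline keeps the
    base[lay.persistent_down] += np.log(2.0)   # down direction detectable
    base[lay.mito] += np.log(cfg.mito_mean_fold)
    base[lay.ligands] = np.log(cfg.lr_base_mean)
    base[lay.receptors] = np.log(cfg.lr_base_mean)

    stage_eff = {}
    for s, stage in enumerate(STAGES):
        eff = np.zeros(cfg.n_genes)
        eff[lay.persistent_up] = s * np.log(cfg.persistent_step)
        eff[lay.persistent_down] = -s * np.log(cfg.persistent_step)
        stage_eff[stage] = eff

    def type_program(ctype: str, stage: str) -> np.ndarray:
        lm = base + stage_eff[stage]
        lm = lm.copy()
        lm[lay.markers[ctype]] += np.log(cfg.marker_fold)
        s = STAGES.index(stage)
        if ctype == "Macrophage":
            act = lay.ligands[:cfg.n_lr_active]
            const = lay.ligands[cfg.n_lr_active:cfg.n_lr_active + cfg.n_lr_constant]
            lm[act] += np.log(cfg.lr_active_fold) + s * np.log(cfg.lr_stage_step)
            lm[const] += np.log(cfg.lr_active_fold)
        if ctype == "Ductal":
            act = lay.receptors[:cfg.n_lr_active]
            const = lay.receptors[cfg.n_lr_active:cfg.n_lr_active + cfg.n_lr_constant]
            lm[act] += np.log(cfg.lr_active_fold) + s * np.log(cfg.lr_stage_step)
            lm[const] += np.log(cfg.lr_active_fold)
        return lm

    def malignant_program(stage: str) -> np.ndarray:
        lm = type_program("Ductal", stage)
        lm[lay.program] += np.log(cfg.program_fold)
        return lm

    return {"base": base, "type": type_program, "malignant": malignant_program}


# ---------------------------------------------------------------------------
# single-cell cohort


def _sample_composition(cfg: CohortConfig, stage: str,
                        rng: np.random.Generator) -> np.ndarray:
    """One sample's cell-type proportion vector with planted jitter.

    Macrophage and NKT share a fixed immune pool whose split varies across
    samples (the planted anti-correlated pair); the remaining immune and
    non-immune types get independent multiplicative jitter and are
    renormalised within their compartments, so stage-level fractions are
    preserved in expectation.
    """
    comp = cfg.stage_composition[stage]
    vec = np.array([comp[t] for t in CELL_TYPES])
    i_mac = CELL_TYPES.index("Macrophage")
    i_nkt = CELL_TYPES.index("NKT")
    immune_idx = [CELL_TYPES.index(t) for t in IMMUNE_TYPES]
    other_immune = [i for i in immune_idx if i not in (i_mac, i_nkt)]
    non_immune = [i for i in range(len(CELL_TYPES)) if i not in immune_idx]

    pool = vec[i_mac] + vec[i_nkt]
    if pool > 0:
        share = vec[i_mac] / pool
        # mean-one lognormal jitter keeps the stage-level share unbiased
        sd = cfg.macrophage_share_sd
        share_s = np.clip(share * np.exp(rng.normal(-0.5 * sd * sd, sd)),
                          0.005, 0.9)
        vec[i_mac] = pool * share_s
        vec[i_nkt] = pool * (1.0 - share_s)
    for group, sd in ((other_immune, cfg.immune_jitter_sd),
                      (non_immune, cfg.other_jitter_sd)):
        mass = vec[group].sum()
        if mass > 0 and sd > 0:
            w = vec[group] * np.exp(rng.normal(0.0, sd, len(group)))
            vec[group] = w * (mass / w.sum())
    return vec / vec.sum()


def generate_single_cell(config: CohortConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate the staged single-cell count matrix and its ground truth.

    Returns an :class:`anndata.AnnData` with raw counts in ``X`` (sparse),
    cell metadata in ``obs`` (sample, stage, batch, true cell type,
    malignancy) and the gene map plus planted-gene flags in ``var``.
    Marker gene sets and the ligand-receptor table ride in ``uns``.
    """
    cfg = config
    lay = _gene_layout(cfg)
    rng = substream(cfg.seed, "cells")
    programs = _log_means(cfg, lay, rng)

    batch_shift = np.exp(rng.normal(0.0, cfg.sc_batch_log_sd,
                                    (cfg.n_batches, cfg.n_genes)))
    stage_prefix = {"Normal": "N", "PRE": "P", "PDAC": "T"}

    rows: list[sp.csr_matrix] = []
    meta: list[dict] = []
    r_disp = 1.0 / cfg.nb_dispersion if cfg.nb_dispersion > 0 else None

    def draw_block(mu: np.ndarray) -> np.ndarray:
        if r_disp is None:
            return rng.poisson(mu)
        p = r_disp / (r_disp + mu)
        return rng.negative_binomial(r_disp, p)

    for stage in STAGES:
        n_cells = cfg.cells_per_stage.get(stage, 0)
        n_samples = cfg.samples_per_stage
        per_sample = np.full(n_samples, n_cells // n_samples)
        per_sample[: n_cells % n_samples] += 1
        for si in range(n_samples):
            sample = f"{stage_prefix[stage]}{si + 1:02d}"
            batch = si % cfg.n_batches
            comp = _sample_composition(cfg, stage, rng)
            counts_per_type = rng.multinomial(per_sample[si], comp)
            for t_idx, ctype in enumerate(CELL_TYPES):
                n_t = counts_per_type[t_idx]
                if n_t == 0:
                    continue
                # split the type block by malignancy label
                labels = np.full(n_t, "normal", dtype=object)
                if stage == "PDAC" and ctype == "Ductal":
                    labels[rng.random(n_t) < cfg.malignant_fraction] = "malignant"
                elif stage == "PRE" and ctype in cfg.malignant_pre_fraction:
                    frac = cfg.malignant_pre_fraction[ctype]
                    labels[rng.random(n_t) < frac] = "malignant_pre"
                for label in ("normal", "malignant_pre", "malignant"):
                    idx = np.where(labels == label)[0]
                    if idx.size == 0:
                        continue
                    if label == "malignant":
                        lm = programs["malignant"](stage)
                        dosage = lay.cnv_mult
                    elif label == "malignant_pre":
                        lm = (cfg.mixing_alpha * programs["malignant"](stage)
                              + (1 - cfg.mixing_alpha) * programs["type"](ctype, stage))
                        dosage = lay.cnv_mult ** cfg.pre_malignant_attenuation
                    else:
                        lm = programs["type"](ctype, stage)
                        dosage = 1.0
                    mean = np.exp(lm) * dosage * batch_shift[batch]
                    size = np.exp(rng.normal(0.0, cfg.cell_size_log_sd, idx.size))
                    mu = np.maximum(size[:, None] * mean[None, :], 1e-12)
                    block = draw_block(mu)
                    rows.append(sp.csr_matrix(block.astype(np.int32)))
                    for _ in idx:
                        meta.append({"sample": sample, "stage": stage,
                                     "batch": f"batch{batch}",
                                     "cell_type": ctype, "malignancy": label})

    X = sp.vstack(rows, format="csr")
    obs = pd.DataFrame(meta)
    obs.index = [f"{r.sample}:{i:05d}" for i, r in enumerate(obs.itertuples())]
    obs.index.name = "barcode"
    var = pd.DataFrame({
        "chromosome": [f"chr{c + 1}" for c in lay.chrom],
        "start": lay.start,
    }, index=pd.Index(lay.names, name="gene"))
    var["persistent"] = "none"
    var.iloc[lay.persistent_up, var.columns.get_loc("persistent")] = "up"
    var.iloc[lay.persistent_down, var.columns.get_loc("persistent")] = "down"
    var["cnv_multiplier"] = lay.cnv_mult
    var["mito"] = False
    var.iloc[lay.mito, var.columns.get_loc("mito")] = True

    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["marker_sets"] = {t: [lay.names[g] for g in lay.markers[t]]
                                for t in CELL_TYPES}
    adata.uns["pathway_sets"] = {
        "MALIGNANCY_PROGRAM": [lay.names[g] for g in lay.program],
        "PERSISTENT_UP": [lay.names[g] for g in lay.persistent_up],
        "PERSISTENT_DOWN": [lay.names[g] for g in lay.persistent_down],
        "LIGAND_RECEPTOR": [lay.names[g] for g in
                            np.concatenate([lay.ligands, lay.receptors])],
    }
    adata.uns["lr_pairs"] = lr_pair_table(cfg, lay)

    truth = GroundTruth(
        cells=obs[["cell_type", "stage", "sample", "malignancy"]].copy(),
        genes=var[["persistent"]].copy(),
        lr_activity=_lr_activity_truth(cfg, lay),
    )
    return adata, truth


def lr_pair_table(cfg: CohortConfig, lay: _GeneLayout | None = None) -> pd.DataFrame:
    """Ligand-receptor pair table (ligand, receptor, pathway)."""
    if lay is None:
        lay = _gene_layout(cfg)
    rows = []
    for i in range(cfg.n_lr_pairs):
        if i < cfg.n_lr_active:
            path = "stage_increasing"
        elif i < cfg.n_lr_active + cfg.n_lr_constant:
            path = "constitutive"
        else:
            path = "inactive"
        rows.append({"ligand": lay.names[lay.ligands[i]],
                     "receptor": lay.names[lay.receptors[i]],
                     "pathway": path})
    return pd.DataFrame(rows)


def _lr_activity_truth(cfg: CohortConfig, lay: _GeneLayout) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_lr_pairs):
        for s, stage in enumerate(STAGES):
            if i < cfg.n_lr_active:
                level = cfg.lr_active_fold * cfg.lr_stage_step ** s
            elif i < cfg.n_lr_active + cfg.n_lr_constant:
                level = cfg.lr_active_fold
            else:
                level = 1.0
            rows.append({"ligand": lay.names[lay.ligands[i]],
                         "receptor": lay.names[lay.receptors[i]],
                         "stage": stage, "activity": level,
                         "active": level > 1.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bulk cohort

#: P(subtype | stage): S1 Normal-dominant, S2 PDAC-enriched, S3 mixed,
#: S4 PRE-dominant.
_SUBTYPE_GIVEN_STAGE = {
    "Normal": {"S1": 0.60, "S2": 0.05, "S3": 0.25, "S4": 0.10},
    "PRE": {"S1": 0.10, "S2": 0.10, "S3": 0.25, "S4": 0.55},
    "PDAC": {"S1": 0.05, "S2": 0.60, "S3": 0.30, "S4": 0.05},
}
SUBTYPES = ("S1", "S2", "S3", "S4")


def generate_bulk(config: CohortConfig,
                  lr_genes: Sequence[str] | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a bulk log2-expression cohort with four planted subtypes.

    Returns ``(matrix, sample_meta, truth)`` where ``matrix`` is samples x
    genes (log2 scale), ``sample_meta`` carries stage and batch labels and
    ``truth`` records the planted subtype of every sample.  Subtypes are
    realised as distinct activation blocks over the ligand-receptor genes;
    batches add per-gene location shifts.
    """
    cfg = config
    lay = _gene_layout(cfg)
    if lr_genes is None:
        lr_idx = np.concatenate([lay.ligands, lay.receptors])
    else:
        name_to_idx = {n: i for i, n in enumerate(lay.names)}
        missing = [g for g in lr_genes if g not in name_to_idx]
        if missing:
            raise ConfigurationError(f"LR genes outside the universe: {missing[:5]}")
        lr_idx = np.array([name_to_idx[g] for g in lr_genes])
    if lr_idx.size < 2:
        raise ConfigurationError("need at least 2 LR genes for subtyping")

    rng = substream(cfg.seed, "bulk")
    base = cfg.bulk_base_mean + rng.normal(0.0, 1.0, cfg.n_genes)

    blocks = np.array_split(np.arange(lr_idx.size), len(SUBTYPES))
    archetype = {}
    for k, sub in enumerate(SUBTYPES):
        eff = np.zeros(cfg.n_genes)
        eff[lr_idx[blocks[k]]] = cfg.bulk_subtype_shift
        archetype[sub] = eff

    stage_effect = {}
    for s, stage in enumerate(STAGES):
        eff = np.zeros(cfg.n_genes)
        eff[lay.persistent_up] = s * cfg.bulk_stage_shift
        eff[lay.persistent_down] = -s * cfg.bulk_stage_shift
        stage_effect[stage] = eff

    batch_eff = rng.normal(0.0, cfg.bulk_batch_sd,
                           (cfg.n_bulk_batches, cfg.n_genes))

    rows, meta = [], []
    for stage in STAGES:
        n = cfg.bulk_samples_per_stage.get(stage, 0)
        probs = [_SUBTYPE_GIVEN_STAGE[stage][s] for s in SUBTYPES]
        subs = rng.choice(len(SUBTYPES), size=n, p=probs)
        for j in range(n):
            sub = SUBTYPES[subs[j]]
            batch = int(rng.integers(cfg.n_bulk_batches))
            # each sample is a mixture of archetypes: its own subtype at
            # full weight plus random minor loadings on the others, so
            # within-subtype heterogeneity is continuous (as in tissue
            # cohorts) rather than point-mass cluster centroids
            effect = archetype[sub].copy()
            for other in SUBTYPES:
                if other != sub:
                    effect = effect + rng.uniform(0, cfg.bulk_mixing_max) \
                        * archetype[other]
            x = (base + effect + stage_effect[stage]
                 + batch_eff[batch]
                 + rng.normal(0.0, cfg.bulk_noise_sd, cfg.n_genes))
            rows.append(x)
            meta.append({"stage": stage, "batch": f"bulkbatch{batch}",
                         "subtype": sub})
    names = [f"BK{i:03d}" for i in range(len(rows))]
    matrix = pd.DataFrame(np.array(rows), index=names, columns=lay.names)
    sample_meta = pd.DataFrame(meta, index=names)[["stage", "batch"]]
    truth = GroundTruth(bulk_samples=pd.DataFrame(meta, index=names))
    return matrix, sample_meta, truth


# ---------------------------------------------------------------------------
# perturbagen reference


def generate_perturbagen_reference(
        config: CohortConfig,
        query_signatures: Mapping[str, pd.Series],
        target: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a perturbagen differential z-score reference.

    ``query_signatures`` maps signature names to full-length per-gene signed
    scores (e.g. log2 fold changes).  Planted reversers are anti-correlated
    with the designated ``target`` signature (the first one by default);
    decoys are uncorrelated noise.  Returns ``(profiles, annotation, truth)``
    with ``profiles`` genes x replicate-profiles.
    """
    cfg = config
    if len(query_signatures) == 0:
        raise ConfigurationError("at least one query signature is required")
    if target is None:
        target = next(iter(query_signatures))
    if target not in query_signatures:
        raise ConfigurationError(f"unknown target signature {target!r}")
    q = query_signatures[target].astype(float)
    genes = q.index
    qz = (q - q.mean()).to_numpy()
    norm = np.linalg.norm(qz)
    if norm == 0:
        raise ConfigurationError("target signature is constant")
    qz = qz / q.std()

    rng = substream(cfg.seed, "reference")
    rho = cfg.reverser_correlation
    cols, ann_rows, data = [], [], []
    for p in range(cfg.n_perturbagens):
        is_rev = p < cfg.n_reversers
        pert = f"REV{p + 1:03d}" if is_rev else f"PERT{p + 1:03d}"
        for rep in range(cfg.n_replicates):
            eps = rng.normal(0.0, 1.0, len(genes))
            if is_rev:
                z = -rho * qz + np.sqrt(1 - rho ** 2) * eps
            else:
                z = eps
            data.append(z)
            cols.append(f"{pert}:rep{rep + 1}")
            ann_rows.append({"profile": f"{pert}:rep{rep + 1}",
                             "perturbagen": pert, "replicate": rep + 1,
                             "pert_class": "compound"})
    profiles = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
    annotation = pd.DataFrame(ann_rows).set_index("profile")
    perts = annotation["perturbagen"].drop_duplicates()
    truth = GroundTruth(perturbagens=pd.DataFrame({
        "perturbagen": perts.to_numpy(),
        "reverser": [p.startswith("REV") for p in perts],
        "target": [target if p.startswith("REV") else "" for p in perts],
    }).set_index("perturbagen"))
    return profiles, annotation, truth
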