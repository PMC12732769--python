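"""Generator contracts: determinism, planted dosage, composition, nulls."""

import numpy as np
import pandas as pd
import pytest

from preneo_atlas import (CohortConfig, generate_bulk,
                          generate_perturbagen_reference,
                          generate_single_cell)
from preneo_atlas.errors import ConfigurationError
from preneo_atlas.synthetic_cohort import CELL_TYPES


def uniform_composition():
    n = len(CELL_TYPES)
    return {s: {t: 1.0 / n for t in CELL_TYPES} for s in ("Normal", "PRE", "PDAC")}


def small_config(**kw):
    base = dict(cells_per_stage={"Normal": 300, "PRE": 300, "PDAC": 300},
                samples_per_stage=6, seed=11)
    base.update(kw)
    return CohortConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_matrices(self):
        a1, _ = generate_single_cell(small_config())
        a2, _ = generate_single_cell(small_config())
        assert (a1.X != a2.X).nnz == 0
        assert a1.obs.equals(a2.obs)

    def test_bulk_same_seed_identical_assignments(self):
        m1, meta1, t1 = generate_bulk(small_config())
        m2, meta2, t2 = generate_bulk(small_config())
        assert np.array_equal(m1.to_numpy(), m2.to_numpy())
        assert t1.bulk_samples["subtype"].equals(t2.bulk_samples["subtype"])

    def test_different_seeds_differ(self):
        a1, _ = generate_single_cell(small_config(seed=1))
        a2, _ = generate_single_cell(small_config(seed=2))
        assert (a1.X != a2.X).nnz > 0


class TestPlantedStructure:
    def test_cnv_dosage_ratio(self):
        """Mean count of a x2-gain gene in malignant cells is ~2x baseline."""
        cfg = CohortConfig(seed=3, cells_per_stage={"Normal": 200, "PRE": 200,
                                                    "PDAC": 8000})
        adata, truth = generate_single_cell(cfg)
        mal = (truth.cells["malignancy"] == "malignant").to_numpy()
        normal_ductal = ((truth.cells["cell_type"] == "Ductal")
                         & (truth.cells["stage"] == "PDAC") & ~mal).to_numpy()
        assert mal.sum() >= 500
        gain = np.where(adata.var["cnv_multiplier"].to_numpy() == 2.0)[0][:5]
        X = adata.X
        m = np.asarray(X[mal][:, gain].mean(axis=0)).ravel()
        r = np.asarray(X[normal_ductal][:, gain].mean(axis=0)).ravel()
        ratios = m / r
        assert np.all(ratios > 1.8) and np.all(ratios < 2.2)

    def test_composition_within_3_percent(self, cohort1):
        cfg = CohortConfig(seed=1)
        truth = cohort1["truth"]
        for stage in ("Normal", "PRE", "PDAC"):
            obs = truth.cells[truth.cells["stage"] == stage]["cell_type"] \
                .value_counts(normalize=True)
            for t, expected in cfg.stage_composition[stage].items():
                assert abs(obs.get(t, 0.0) - expected) < 0.03

    def test_persistent_genes_monotone_in_means(self, cohort1):
        adata, truth = cohort1["adata"], cohort1["truth"]
        up = truth.genes.index[truth.genes["persistent"] == "up"]
        idx = [adata.var_names.get_loc(g) for g in up]
        stage_means = {}
        for stage in ("Normal", "PRE", "PDAC"):
            m = (adata.obs["stage"] == stage).to_numpy()
            stage_means[stage] = np.asarray(adata.X[m][:, idx].mean(axis=0)).ravel()
        assert np.all(stage_means["PRE"] > stage_means["Normal"])
        assert np.all(stage_means["PDAC"] > stage_means["PRE"])


class TestNullConfiguration:
    def test_no_planted_structure(self):
        cfg = small_config(marker_fold=1.0, cnv_segments=[], persistent_step=1.0,
                           stage_composition=uniform_composition(),
                           macrophage_share_sd=0.0, immune_jitter_sd=0.0,
                           other_jitter_sd=0.0)
        adata, truth = generate_single_cell(cfg)
        up = truth.genes.index[truth.genes["persistent"] == "up"]
        idx = [adata.var_names.get_loc(g) for g in up]
        means = []
        for stage in ("Normal", "PRE", "PDAC"):
            m = (adata.obs["stage"] == stage).to_numpy()
            means.append(np.asarray(adata.X[m][:, idx].mean(axis=0)).ravel())
        # no stage effect: mean ratios stay within sampling error of 1
        for a, b in ((0, 1), (1, 2)):
            ratio = means[a] / means[b]
            assert np.all(ratio > 0.8) and np.all(ratio < 1.25)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_genes=300),                       # planted blocks do not fit
        dict(cells_per_stage={"Normal": 0, "PRE": 10, "PDAC": 10}),
        dict(mixing_alpha=1.5),
        dict(cnv_segments=[(99, "gain", 2.0)]),
        dict(cnv_segments=[(1, "gain", -1.0)]),
        dict(n_lr_active=40, n_lr_constant=40),
        dict(n_reversers=500),
    ])
    def test_contradictory_config_raises(self, kw):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kw)

    def test_composition_must_sum_to_one(self):
        comp = uniform_composition()
        comp["PRE"]["B"] += 0.2
        with pytest.raises(ConfigurationError):
            CohortConfig(stage_composition=comp)


class TestBulk:
    def test_noiseless_limit_within_subtype_correlation(self):
        cfg = small_config(bulk_noise_sd=1e-12, bulk_batch_sd=0.0,
                           bulk_mixing_max=0.0,
                           bulk_samples_per_stage={"Normal": 12, "PRE": 12,
                                                   "PDAC": 12})
        matrix, meta, truth = generate_bulk(cfg)
        sub = truth.bulk_samples
        for s in sub["subtype"].unique():
            rows = matrix[(sub["subtype"] == s).to_numpy()
                          & (sub["stage"] == "PDAC").to_numpy()]
            if len(rows) >= 2:
                c = np.corrcoef(rows.to_numpy())
                assert np.allclose(c, 1.0, atol=1e-6)

    def test_planted_subtypes_positive_silhouette(self):
        from sklearn.metrics import silhouette_score
        cfg = CohortConfig(seed=2)
        matrix, meta, truth = generate_bulk(cfg)
        # silhouette of planted subtypes on the LR genes used for subtyping
        from preneo_atlas.synthetic_cohort import lr_pair_table
        tab = lr_pair_table(cfg)
        genes = sorted(set(tab["ligand"]) | set(tab["receptor"]))
        s = silhouette_score(matrix[genes], truth.bulk_samples["subtype"])
        assert s > 0

    def test_too_few_lr_genes_raises(self):
        with pytest.raises(ConfigurationError):
            generate_bulk(small_config(), lr_genes=["G0000"])


class TestPerturbagenReference:
    def test_reverser_anticorrelated_with_target(self):
        cfg = small_config()
        rng = np.random.default_rng(0)
        q = pd.Series(rng.normal(size=cfg.n_genes),
                      index=[f"G{i:04d}" for i in range(cfg.n_genes)])
        prof, ann, truth = generate_perturbagen_reference(cfg, {"sig": q})
        rev_profiles = ann.index[ann["perturbagen"].str.startswith("REV")]
        for p in rev_profiles[:6]:
            assert np.corrcoef(prof[p], q)[0, 1] <= -0.8
        decoys = ann.index[~ann["perturbagen"].str.startswith("REV")]
        decoy_r = [np.corrcoef(prof[p], q)[0, 1] for p in decoys[:20]]
        assert np.max(np.abs(decoy_r)) < 0.3

    def test_zero_reversers_empty_truth(self):
        cfg = small_config(n_reversers=0)
        q = pd.Series(np.arange(cfg.n_genes, dtype=float),
                      index=[f"G{i:04d}" for i in range(cfg.n_genes)])
        _, _, truth = generate_perturbagen_reference(cfg, {"sig": q})
        assert truth.perturbagens["reverser"].sum() == 0

    def test_counts_as_configured(self):
        cfg = small_config(n_perturbagens=20, n_reversers=4, n_replicates=2)
        q = pd.Series(np.arange(cfg.n_genes, dtype=float),
                      index=[f"G{i:04d}" for i in range(cfg.n_genes)])
        prof, ann, truth = generate_perturbagen_reference(cfg, {"sig": q})
        assert prof.shape[1] == 40
        assert truth.perturbagens["reverser"].sum() == 4
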