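"""Positional CNV smoothing, malignancy calling and cluster designation."""

import numpy as np
import pandas as pd
import pytest

from preneo_atlas import call_malignant, designate_malignant_pre, infer_cnv
from preneo_atlas.cnv_malignancy import CnvProfiles, _moving_average
from preneo_atlas.errors import InputDataError


def toy_gene_map(n_genes, per_chr=200):
    names = [f"G{i:04d}" for i in range(n_genes)]
    return pd.DataFrame({
        "chromosome": [f"chr{i // per_chr + 1}" for i in range(n_genes)],
        "start": [(i % per_chr) + 1 for i in range(n_genes)],
    }, index=names), names


def noiseless_counts(n_ref=30, n_query=5, n_genes=1000, base=50.0,
                     gain_span=None, gain_mult=2.0):
    """Deterministic counts: reference cells flat, query cells with a gain."""
    X = np.full((n_ref + n_query, n_genes), base)
    if gain_span is not None:
        X[n_ref:, gain_span] *= gain_mult
    return X


class TestInferCnv:
    def test_reference_cells_have_zero_profile_and_burden(self):
        gm, names = toy_gene_map(1000)
        X = noiseless_counts()
        ref = np.arange(35) < 30
        prof = infer_cnv(X, gm, ref, names, window=51, expr_min=0.1)
        assert np.allclose(prof.matrix[:30], 0.0, atol=1e-9)
        assert np.allclose(prof.burden[:30], 0.0, atol=1e-12)

    def test_noiseless_gain_recovers_one_log2_unit(self):
        gm, names = toy_gene_map(1000)
        gain = np.arange(200)                       # whole first chromosome
        X = noiseless_counts(gain_span=gain)
        ref = np.arange(35) < 30
        prof = infer_cnv(X, gm, ref, names, window=51)
        central = prof.matrix[30:, 60:140]          # away from segment edges
        assert np.all(np.abs(central - 1.0) < 0.05)

    def test_window_one_is_identity_on_clipped_ratios(self):
        gm, names = toy_gene_map(400, per_chr=100)
        rng = np.random.default_rng(0)
        X = rng.poisson(30.0, size=(40, 400)).astype(float) + 1
        ref = np.arange(40) < 30
        p1 = infer_cnv(X, gm, ref, names, window=1)
        M = _moving_average(np.arange(12.0)[None, :], 1)
        assert np.allclose(M, np.arange(12.0))
        assert p1.matrix.shape == (40, 400)

    def test_profile_invariant_to_gene_input_order(self):
        gm, names = toy_gene_map(600, per_chr=200)
        X = noiseless_counts(n_genes=600, gain_span=np.arange(200))
        ref = np.arange(35) < 30
        base = infer_cnv(X, gm, ref, names)
        perm = np.random.default_rng(1).permutation(600)
        shuffled = infer_cnv(X[:, perm], gm, ref, list(np.array(names)[perm]))
        assert np.allclose(base.matrix, shuffled.matrix)

    def test_linearity_uniform_scaling_recentred_away(self):
        """Scaling all counts of a cell cancels in the re-centred profile."""
        gm, names = toy_gene_map(1000)
        X = noiseless_counts(gain_span=np.arange(200))
        Xs = X.copy()
        Xs[30:] *= 3.0                             # library-size style scaling
        ref = np.arange(35) < 30
        a = infer_cnv(X, gm, ref, names)
        b = infer_cnv(Xs, gm, ref, names)
        assert np.allclose(a.matrix, b.matrix, atol=1e-9)

    def test_small_reference_raises(self):
        gm, names = toy_gene_map(400, per_chr=100)
        X = noiseless_counts(n_ref=10, n_query=2, n_genes=400)
        with pytest.raises(InputDataError):
            infer_cnv(X, gm, np.arange(12) < 10, names)


class TestCallMalignant:
    def test_no_calls_when_identical_to_reference(self):
        gm, names = toy_gene_map(1000)
        X = noiseless_counts()
        ref = np.arange(35) < 30
        prof = infer_cnv(X, gm, ref, names)
        stages = np.array(["PDAC"] * 35)
        with pytest.warns(UserWarning, match="zero variance"):
            flags = call_malignant(prof, stages)
        assert not flags.any()

    def test_infinite_threshold_gives_zero_calls(self, cohort1):
        adata = cohort1["adata"]
        ct = cohort1["cell_types"]
        prof = infer_cnv(adata.X, adata.var[["chromosome", "start"]],
                         ct == "B", adata.var_names)
        flags = call_malignant(prof, cohort1["stages"], k_sd=np.inf)
        assert flags.sum() == 0

    def test_non_eligible_stage_never_called(self, cohort1):
        adata = cohort1["adata"]
        ct = cohort1["cell_types"]
        prof = infer_cnv(adata.X, adata.var[["chromosome", "start"]],
                         ct == "B", adata.var_names)
        flags = call_malignant(prof, cohort1["stages"])
        assert not flags[cohort1["stages"] != "PDAC"].any()


class TestDesignation:
    def _setup(self):
        rng = np.random.default_rng(2)
        norm = rng.normal(0, 1.0, (60, 30))
        norm[40:] += 3.0                           # malignant block distinct
        malignant = np.arange(60) >= 40
        return norm, malignant

    def test_low_pre_fraction_never_designated(self):
        norm, mal = self._setup()
        stages = np.array(["PRE"] * 8 + ["PDAC"] * 12 + ["PRE"] * 20
                          + ["PDAC"] * 20)
        clusters = np.array([0] * 20 + [1] * 20 + [2] * 20)
        calls = designate_malignant_pre(norm, clusters, stages, mal)
        c0 = next(c for c in calls if c.cluster == 0)
        assert c0.pre_fraction == pytest.approx(0.4)
        assert c0.designation == "not_preneoplastic"

    def test_r_exactly_at_threshold_stays_preneoplastic(self):
        calls_from = designate_malignant_pre
        norm = np.vstack([np.tile([1.0, 2, 3, 4], (10, 1)),
                          np.tile([1.0, 2, 3, 4], (10, 1))])
        stages = np.array(["PRE"] * 10 + ["PDAC"] * 10)
        clusters = np.array([0] * 10 + [1] * 10)
        mal = np.arange(20) >= 10
        calls = calls_from(norm, clusters, stages, mal, r_min=1.0)
        c0 = next(c for c in calls if c.cluster == 0)
        # r equals r_min exactly (identical profiles): strict rule applies
        assert c0.r == pytest.approx(1.0)
        assert c0.designation == "preneoplastic"

    def test_self_profile_designated_when_pre_dominant(self):
        norm, mal = self._setup()
        stages = np.array(["PDAC"] * 40 + ["PRE"] * 20)
        clusters = np.array([0] * 40 + [1] * 20)
        norm[40:] = norm[40:] - norm[40:].mean(0) + norm[:5].mean(0) * 0 + 3.0
        calls = designate_malignant_pre(norm, clusters, stages, mal)
        c1 = next(c for c in calls if c.cluster == 1)
        assert c1.pre_fraction == 1.0

    def test_no_malignant_cells_raises(self):
        norm, _ = self._setup()
        with pytest.raises(InputDataError, match="call_malignant"):
            designate_malignant_pre(norm, np.zeros(60, int),
                                    np.array(["PRE"] * 60), np.zeros(60, bool))

    def test_cnv_profile_correlation_option(self):
        norm, mal = self._setup()
        stages = np.array(["PRE"] * 40 + ["PDAC"] * 20)
        clusters = np.array([0] * 20 + [1] * 20 + [2] * 20)
        prof = CnvProfiles(matrix=norm.copy(), gene_order=np.arange(30),
                           chromosomes=np.array(["chr1"] * 30),
                           burden=(norm ** 2).mean(1),
                           reference_mask=np.arange(60) < 10)
        calls = designate_malignant_pre(None, clusters, stages, mal,
                                        cnv_profiles=prof)
        assert len(calls) == 3
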