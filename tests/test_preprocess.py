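"""QC, normalisation, HVG, clustering, annotation and Wilcoxon DE."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score

from preneo_atlas import (QcThresholds, annotate_clusters, cluster_cells,
                          lognormalize, qc_filter, select_hvgs, wilcoxon_de)
from preneo_atlas.errors import (ConfigurationError, EmptyResultWarning,
                                 InputDataError)
from preneo_atlas.preprocess import _exact_ranksum_p

GENES = [f"G{i}" for i in range(48)] + ["MT-0", "MT-1"]


def make_cell(n_detected, mito_frac=0.0, total=500):
    """A 50-gene cell with a given detected-gene count and mito fraction."""
    x = np.zeros(50)
    mito = total * mito_frac
    rest = total - mito
    n_rest = max(n_detected - (2 if mito > 0 else 0), 1)
    x[:n_rest] = rest / n_rest
    if mito > 0:
        x[48:50] = mito / 2
    return x


class TestQc:
    def test_low_detected_removed_boundary_retained(self):
        genes = [f"G{i}" for i in range(300)]
        low = np.zeros(300); low[:150] = 1          # 150 detected -> removed
        edge = np.zeros(300); edge[:200] = 1        # exactly 200 -> retained
        keep, rep = qc_filter(np.vstack([low, edge]), genes,
                              QcThresholds(min_genes=200, max_genes=250))
        assert list(keep) == [False, True]
        assert rep.removed_low_genes == 1

    def test_mito_fraction_exactly_at_cap_removed(self):
        # integer counts keep the 10% fraction exact in floating point
        at_cap = np.zeros(50); at_cap[:45] = 10; at_cap[48:] = 25   # 50/500
        below = np.zeros(50); below[:45] = 10; below[48:] = 10      # 20/470
        keep, rep = qc_filter(np.vstack([at_cap, below]), GENES,
                              QcThresholds(min_genes=10, max_genes=50))
        assert list(keep) == [False, True]
        assert rep.removed_mito == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(60, 50)).astype(float)
        keep, _ = qc_filter(X, GENES, QcThresholds(min_genes=10, max_genes=50))
        keep2, rep2 = qc_filter(X[keep], GENES,
                                QcThresholds(min_genes=10, max_genes=50))
        assert keep2.all()
        assert rep2.n_retained == keep.sum()

    def test_empty_matrix_raises_and_all_removed_warns(self):
        with pytest.raises(InputDataError):
            qc_filter(np.empty((0, 5)), ["a"] * 5)
        with pytest.warns(EmptyResultWarning):
            keep, _ = qc_filter(np.ones((3, 5)), [f"G{i}" for i in range(5)],
                                QcThresholds(min_genes=4, max_genes=4))
        assert not keep.any()


class TestLognormalize:
    def test_closed_form(self):
        out = lognormalize(np.array([[100.0, 9900.0]]), scale=1e4)
        assert out[0, 0] == pytest.approx(np.log(101.0), abs=1e-9)
        assert lognormalize(np.array([[0.0, 10.0]]))[0, 0] == 0.0

    def test_scale_invariance_and_rank_preservation(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(3.0, size=(1, 30)).astype(float) + 1
        doubled = lognormalize(2 * x)
        assert np.allclose(doubled, lognormalize(x))
        out = lognormalize(x)[0]
        from scipy.stats import rankdata
        assert np.array_equal(rankdata(out), rankdata(x[0]))

    def test_zero_total_names_cell(self):
        with pytest.raises(InputDataError, match="cellB"):
            lognormalize(np.array([[1.0, 2.0], [0.0, 0.0]]),
                         cell_names=["cellA", "cellB"])


class TestHvg:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(2.0, (100, 10)).astype(float)
        X[:, 3] = 7.0
        picked = select_hvgs(X, n=9)
        assert 3 not in picked

    def test_n_equals_total_returns_all(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(2.0, (50, 12)).astype(float)
        assert sorted(select_hvgs(X, n=12)) == list(range(12))

    def test_bimodal_ranks_above_poisson_of_equal_mean(self):
        rng = np.random.default_rng(4)
        n = 400
        poisson = rng.poisson(5.0, n)
        bimodal = np.where(rng.random(n) < 0.5, 0, 10).astype(float)
        filler = rng.poisson(5.0, (n, 6))
        X = np.column_stack([poisson, bimodal, filler]).astype(float)
        order = list(select_hvgs(X, n=8))
        assert order.index(1) < order.index(0)

    def test_too_many_requested_raises(self):
        with pytest.raises(ConfigurationError):
            select_hvgs(np.ones((5, 4)), n=5)


class TestClustering:
    def test_two_separated_blobs_give_two_matching_clusters(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.3, (60, 10)),
                       rng.normal(6, 0.3, (60, 10))])
        a = cluster_cells(X, None, n_pcs=5, resolution=0.9, seed=0)
        assert a.n_clusters == 2
        assert len(set(a.labels[:60])) == 1 and len(set(a.labels[60:])) == 1

    def test_low_resolution_merges_connected_graph(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1.0, (80, 8))
        a = cluster_cells(X, None, n_pcs=5, resolution=1e-3, seed=0)
        assert a.n_clusters == 1

    def test_duplicated_cells_co_cluster(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 0.3, (40, 6)),
                       rng.normal(5, 0.3, (40, 6))])
        a = cluster_cells(np.vstack([X, X]), None, n_pcs=4, seed=0)
        assert (a.labels[:80] == a.labels[80:]).all()

    def test_invariant_to_cell_and_gene_order(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.4, (50, 12)),
                       rng.normal(4, 0.4, (50, 12)),
                       rng.normal(-4, 0.4, (50, 12))])
        base = cluster_cells(X, None, n_pcs=5, seed=0)
        perm = rng.permutation(150)
        shuffled = cluster_cells(X[perm], None, n_pcs=5, seed=0)
        assert adjusted_rand_score(base.labels[perm], shuffled.labels) == 1.0
        gperm = rng.permutation(12)
        gshuf = cluster_cells(X[:, gperm], None, n_pcs=5, seed=0)
        assert adjusted_rand_score(base.labels, gshuf.labels) == 1.0

    def test_too_few_cells_raises(self):
        with pytest.raises(InputDataError):
            cluster_cells(np.ones((5, 4)), None, k_neighbors=20)


class TestAnnotation:
    def test_marker_dominant_cluster_labelled(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 0.1, (30, 6))
        X[:15, :2] += 5.0            # cluster 0 expresses type-A markers
        labels = np.array([0] * 15 + [1] * 15)
        genes = [f"g{i}" for i in range(6)]
        ann = annotate_clusters(X, labels, {"A": ["g0", "g1"],
                                            "B": ["g4", "g5"]}, genes)
        assert ann.loc[0, "cell_type"] == "A"

    def test_all_zero_cluster_ties_lexicographic_flagged(self):
        X = np.zeros((20, 4))
        labels = np.zeros(20, dtype=int)
        ann = annotate_clusters(X, labels,
                                {"Beta": ["g0"], "Alpha": ["g1"]},
                                ["g0", "g1", "g2", "g3"])
        assert ann.loc[0, "cell_type"] == "Alpha"
        assert bool(ann.loc[0, "low_confidence"])

    def test_unmatched_marker_set_skipped_with_warning(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.warns(UserWarning, match="no matching genes"):
            ann = annotate_clusters(X, np.zeros(20, dtype=int),
                                    {"A": ["g0"], "Z": ["absent"]},
                                    ["g0", "g1", "g2"])
        assert "Z" not in ann["cell_type"].values

    def test_default_cohort_annotation_accuracy(self, cohort1):
        adata = cohort1["adata"]
        assign = cluster_cells(cohort1["norm"], cohort1["hvgs"], seed=1,
                               batch=adata.obs["batch"].to_numpy())
        ann = annotate_clusters(cohort1["norm"], assign.labels,
                                adata.uns["marker_sets"], adata.var_names)
        called = ann.loc[assign.labels, "cell_type"].to_numpy()
        accuracy = (called == cohort1["cell_types"]).mean()
        assert accuracy >= 0.95


def enumeration_ranksum_p(a, b):
    """Independent oracle: full enumeration of rank-sum splits."""
    pool = np.concatenate([a, b])
    ranks = rankdata(pool)
    n = len(a)
    obs = ranks[:n].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in combinations(range(len(pool)), n)])
    p = 2 * min((sums <= obs).mean(), (sums >= obs).mean())
    return min(1.0, p)


class TestWilcoxonDe:
    def test_exact_example_p_is_point_one(self):
        X = np.log1p(np.array([[1.0], [2], [3], [4], [5], [6]]))
        tab = wilcoxon_de(X, [0, 1, 2], [3, 4, 5], logfc_min=0.0, min_pct=0.0)
        assert tab["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_not_tested(self):
        X = np.tile(np.log1p(np.arange(1.0, 7.0))[:, None], (1, 3))
        tab = wilcoxon_de(X, [0, 1, 2], [0, 1, 2])
        assert not tab["tested"].any()

    def test_min_pct_excludes_sparsely_expressed_gene(self):
        rng = np.random.default_rng(10)
        X = np.zeros((40, 1))
        X[:8, 0] = np.log1p(rng.poisson(30, 8) + 30.0)    # 40% of group A
        X[20:28, 0] = np.log1p(rng.poisson(5, 8) + 5.0)   # 40% of group B
        tab = wilcoxon_de(X, np.arange(20), np.arange(20, 40),
                          min_pct=0.5, logfc_min=0.0)
        assert not tab["tested"].iloc[0]

    def test_empty_or_tiny_group_raises(self):
        X = np.ones((6, 2))
        with pytest.raises(InputDataError):
            wilcoxon_de(X, [], [0, 1, 2])
        with pytest.raises(InputDataError):
            wilcoxon_de(X, [0, 1], [2, 3, 4])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(3, 5), st.integers(3, 5), st.integers(0, 10**6))
    def test_exact_p_matches_enumeration(self, na, nb, seed):
        """Exact rank-sum p equals the full-enumeration oracle with ties."""
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, na).astype(float)
        b = rng.integers(0, 6, nb).astype(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            return
        assert _exact_ranksum_p(a, b) == pytest.approx(
            enumeration_ranksum_p(a, b), abs=1e-12)

    def test_padj_at_least_p(self, cohort1):
        stages = cohort1["stages"]
        ct = cohort1["cell_types"]
        a = np.where((ct == "Ductal") & (stages == "PDAC"))[0]
        b = np.where((ct == "Ductal") & (stages == "Normal"))[0]
        tab = wilcoxon_de(cohort1["norm"], a, b)
        tested = tab[tab["tested"]]
        assert (tested["p_adj"] >= tested["p"] - 1e-12).all()
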