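"""SNP + hash demultiplexing stages and their planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from mpalkit import synthetic
from mpalkit.demux import (
    MULTIPLET,
    UNASSIGNED,
    ClusterTree,
    DemuxConfig,
    assign_clusters,
    clr_normalize,
    cluster_cells,
    demux,
    estimate_hash_background,
    hotelling_t2,
    impute_knn,
    refine_snps,
    select_informative_snps,
    snp_cluster_association,
    split_clusters,
)


class TestCLR:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((1, 1, 1), (0.0, 0.0, 0.0)),
            ((0, 0, 0), (0.0, 0.0, 0.0)),
            ((3, 1), (0.34657359, -0.34657359)),
        ],
    )
    def test_hand_values(self, row, expected):
        out = clr_normalize(pd.DataFrame([row])).to_numpy()[0]
        assert np.allclose(out, expected, atol=1e-8)

    def test_row_means_zero(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, (50, 6)))
        clr = clr_normalize(counts)
        assert np.abs(clr.mean(axis=1)).max() < 1e-10

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            clr_normalize(pd.DataFrame([[-1, 2]]))


class TestSNPSelection:
    def test_frequency_band(self):
        n = 1000
        G = pd.DataFrame(
            {
                "rare": [1.0] * 50 + [0.0] * 950,  # 5% -> dropped
                "common": [1.0] * 850 + [0.0] * 150,  # 85% -> dropped
                "mid": [1.0] * 500 + [0.0] * 500,  # 50% -> kept
            }
        )
        assert select_informative_snps(G) == ["mid"]

    def test_no_informative_snp_errors(self):
        G = pd.DataFrame({"v": [1.0] * 99 + [0.0]})
        with pytest.raises(ValueError, match="demultiplex"):
            select_informative_snps(G)


class TestImputation:
    def test_majority_vote(self):
        # cell 5 missing SNP b; its 5 nearest share SNP a; majority of b is 1
        G = pd.DataFrame(
            {
                "a": [1, 1, 1, 1, 1, 1.0],
                "b": [1, 1, 0, 1, 0, np.nan],
                "c": [1, 1, 1, 1, 1, 1.0],
            }
        )
        out = impute_knn(G, k=5)
        assert out.loc[5, "b"] == 1.0

    def test_no_missing_identity(self, rng):
        G = pd.DataFrame(rng.integers(0, 2, (30, 5)).astype(float))
        pd.testing.assert_frame_equal(impute_knn(G), G)

    def test_tie_breaks_to_wild_type(self):
        G = pd.DataFrame(
            {
                "a": [1, 1, 1, 1, 1.0],
                "b": [1, 1, 0, 0, np.nan],
            }
        )
        out = impute_knn(G, k=4)
        assert out.loc[4, "b"] == 0.0

    def test_planted_block_recovery(self, rng):
        n, m = 500, 30
        block = rng.integers(0, 2, (2, m)).astype(float)
        labels = rng.integers(0, 2, n)
        truth = block[labels]
        observed = truth.copy()
        mask = rng.random((n, m)) < 0.10
        observed[mask] = np.nan
        out = impute_knn(pd.DataFrame(observed), k=5).to_numpy()
        agree = (out[mask] == truth[mask]).mean()
        assert agree >= 0.99

    def test_unobserved_cell_errors(self):
        G = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, np.nan]})
        with pytest.raises(ValueError, match="no observed SNP"):
            impute_knn(G)


class TestClustering:
    def test_disjoint_blocks_recovered(self, rng):
        patterns = np.eye(3).repeat(10, axis=1)  # 3 disjoint 10-SNP blocks
        labels = rng.integers(0, 3, 300)
        G = pd.DataFrame(patterns[labels])
        tree = cluster_cells(G, k=3)
        assert adjusted_rand_score(labels, tree.labels) == 1.0

    def test_k_equals_n_degenerate(self, rng):
        G = pd.DataFrame(rng.random((8, 4)) + 0.1)
        tree = cluster_cells(G, k=8)
        assert len(np.unique(tree.labels)) == 8

    def test_duplicates_co_clustered(self, rng):
        base = rng.random((10, 4)) + 0.1
        G = pd.DataFrame(np.vstack([base, base[0]]))
        tree = cluster_cells(G, k=5)
        assert tree.labels[0] == tree.labels[-1]

    def test_zero_row_errors(self):
        G = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="zero-norm"):
            cluster_cells(G, k=2)

    def test_ward_heights_monotone(self, rng):
        G = pd.DataFrame(rng.integers(0, 2, (60, 12)).astype(float) + 0.01)
        Z = cluster_cells(G, k=3).linkage_matrix
        assert (np.diff(Z[:, 2]) >= -1e-12).all()


class TestSNPRefinement:
    def test_perfect_separation_selected(self):
        labels = np.repeat([0, 1, 2], 1000)
        snp = (labels == 0).astype(float)
        assert snp_cluster_association(snp, labels) < 1e-12

    def test_null_snp_not_selected(self):
        labels = np.repeat([0, 1, 2], 100)
        snp = np.tile([0.0, 1.0], 150)  # 50% everywhere
        assert snp_cluster_association(snp, labels) > 0.5

    def test_exact_matches_fisher_2x2(self, rng):
        # with k=2 clusters the exact 2xk test reduces to Fisher's exact test
        for _ in range(25):
            labels = rng.integers(0, 2, 40)
            snp = rng.integers(0, 2, 40).astype(float)
            if len(np.unique(labels)) < 2:
                continue
            table = [
                [int(((snp == 1) & (labels == c)).sum()) for c in (0, 1)],
                [int(((snp == 0) & (labels == c)).sum()) for c in (0, 1)],
            ]
            _, expected = stats.fisher_exact(table)
            got = snp_cluster_association(snp, labels)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_alpha_one_selects_all(self, rng):
        G = pd.DataFrame(rng.integers(0, 2, (50, 6)).astype(float))
        labels = rng.integers(0, 3, 50)
        selected, _ = refine_snps(G, labels, alpha=1.0)
        assert selected == list(G.columns)

    def test_no_passer_falls_back_with_warning(self, rng):
        G = pd.DataFrame(rng.integers(0, 2, (60, 4)).astype(float))
        labels = rng.integers(0, 3, 60)
        with pytest.warns(UserWarning, match="keeping all"):
            selected, _ = refine_snps(G, labels, alpha=1e-300)
        assert selected == list(G.columns)


class TestHotelling:
    def test_univariate_equals_squared_t(self):
        x, y = np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]])
        t2, _, _ = hotelling_t2(x, y)
        assert t2 == pytest.approx(13.5, abs=1e-12)

    def test_matches_squared_t_on_random_data(self, rng):
        for _ in range(20):
            x = rng.normal(size=(15, 1))
            y = rng.normal(size=(12, 1))
            t2, _, p2 = hotelling_t2(x, y)
            t, p = stats.ttest_ind(x[:, 0], y[:, 0], equal_var=True)
            assert abs(t2 - t**2) < 1e-9
            assert p2 == pytest.approx(p, abs=1e-9)

    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=(10, 3))
        t2, _, p = hotelling_t2(x, x.copy())
        assert t2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_dimension_precondition(self, rng):
        with pytest.raises(ValueError, match="n1 \\+ n2"):
            hotelling_t2(rng.normal(size=(2, 4)), rng.normal(size=(2, 4)))


class TestSplitAndAssign:
    @staticmethod
    def _tree(values: pd.DataFrame, k: int) -> ClusterTree:
        jitter = pd.DataFrame(
            values.to_numpy() + 0.5, index=values.index, columns=values.columns
        )
        return cluster_cells(jitter, k)

    def test_null_children_not_split(self, rng):
        clr = pd.DataFrame(rng.normal(size=(200, 3)))
        tree = cluster_cells(pd.DataFrame(rng.random((200, 6)) + 0.1), k=2)
        out = split_clusters(tree, clr, DemuxConfig(k_pool=2))
        assert len(np.unique(out.labels)) == 2

    def test_planted_hash_split_recovered(self, rng):
        # three genotype groups but an initial cut at k=2: the merged node's
        # children separate the remaining two groups, and their 4-SD hash
        # difference licenses the extra split
        n = 300
        truth = rng.integers(0, 3, n)
        geno = np.zeros((n, 12))
        for g in range(3):
            geno[truth == g, g * 4 : g * 4 + 4] = 1.0
        clr = rng.normal(size=(n, 3))
        for g in range(3):
            clr[truth == g, g] += 4.0
        tree = cluster_cells(pd.DataFrame(geno + 0.01 * rng.random((n, 12))), k=2)
        assert len(np.unique(tree.labels)) == 2
        out = split_clusters(tree, pd.DataFrame(clr), DemuxConfig(k_pool=2))
        assert adjusted_rand_score(truth, out.labels) >= 0.95

    def test_small_cluster_never_split(self, rng):
        # 15 cells whose best split is 8/7: below the 10-cell floor
        geno = pd.DataFrame(rng.random((15, 4)) + 0.1)
        clr = pd.DataFrame(np.vstack([rng.normal(0, 1, (8, 2)),
                                      rng.normal(8, 1, (7, 2))]))
        tree = cluster_cells(geno, k=1)
        out = split_clusters(tree, clr, DemuxConfig(k_pool=2, min_cluster=10))
        # the initial cut may give 2 nodes, but none smaller than 10 may split
        sizes = np.bincount(out.labels)[1:]
        assert (sizes[sizes > 0] >= 1).all() and len(np.unique(out.labels)) <= 2

    def test_assignment_rules(self):
        cells = pd.Index([f"c{i}" for i in range(30)])
        tree = ClusterTree(
            linkage_matrix=np.empty((0, 4)),
            cells=cells,
            labels=np.repeat([1, 2, 3], 10),
        )
        clr = pd.DataFrame(0.0, index=cells, columns=["h1", "h2"])
        clr.iloc[0:10, 0] = 5.0  # cluster 1: h1 only -> patient h1
        clr.iloc[10:20, :] = 5.0  # cluster 2: both -> multiplet
        # cluster 3: exactly 50% of cells above threshold -> unassigned
        clr.iloc[20:25, 0] = 5.0
        res = assign_clusters(tree, clr, {"h1": 1.0, "h2": 1.0})
        assert (res.labels.iloc[0:10] == "h1").all()
        assert (res.labels.iloc[10:20] == MULTIPLET).all()
        assert (res.labels.iloc[20:30] == UNASSIGNED).all()

    def test_missing_threshold_errors(self):
        cells = pd.Index(["a", "b"])
        tree = ClusterTree(np.empty((0, 4)), cells, np.array([1, 1]))
        clr = pd.DataFrame(0.0, index=cells, columns=["h1"])
        with pytest.raises(ValueError, match="threshold"):
            assign_clusters(tree, clr, {})


class TestBackground:
    def test_constant_data_degenerate(self):
        mode, thr = estimate_hash_background(np.full(60, 2.5))
        assert mode == 2.5 and thr == 2.5

    def test_too_few_values_error(self):
        with pytest.raises(ValueError, match="50"):
            estimate_hash_background(np.zeros(10))

    def test_bimodal_left_mode_near_zero(self, rng):
        v = np.concatenate([rng.normal(0, 1, 2500), rng.normal(6, 1, 2500)])
        mode, thr = estimate_hash_background(v)
        assert abs(mode) < 0.5
        assert abs(thr - 1.645) < 0.5


class TestFullDemux:
    def test_partition_property(self, small_pool):
        _, (geno, hashes, truth) = small_pool
        res = demux(geno, hashes)
        assert res.labels.index.equals(geno.index)
        assert res.labels.notna().all()

    def test_singlet_accuracy_small_pool(self, small_pool):
        _, (geno, hashes, truth) = small_pool
        res = demux(geno, hashes)
        singlets = truth.cells.index[~truth.cells["is_doublet"]]
        acc = (res.labels.loc[singlets] == truth.cells.loc[singlets, "patient"]).mean()
        assert acc >= 0.95

    def test_noiseless_pool_perfect(self):
        cfg = synthetic.PoolSimConfig(
            cells_per_patient=100, missing_rate=0.0, doublet_rate=0.0, seed=5
        )
        geno, hashes, truth = synthetic.simulate_pool(cfg)
        res = demux(geno, hashes)
        acc = (res.labels == truth.cells["patient"]).mean()
        assert acc == 1.0
        assert not (res.labels == MULTIPLET).any()

    def test_label_invariance_under_cell_permutation(self):
        cfg = synthetic.PoolSimConfig(cells_per_patient=80, seed=31)
        geno, hashes, truth = synthetic.simulate_pool(cfg)
        res1 = demux(geno, hashes)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(geno))
        res2 = demux(geno.iloc[perm], hashes.iloc[perm])
        common = (res1.labels == res2.labels.loc[res1.labels.index])
        assert common.mean() > 0.99

    def test_mismatched_barcodes_rejected(self, small_pool):
        _, (geno, hashes, _) = small_pool
        with pytest.raises(ValueError, match="barcode"):
            demux(geno.iloc[:-1], hashes)
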