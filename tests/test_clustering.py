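"""Group-discovery contracts: k-means, consensus, CDF area, gap, embedding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from methgroup.clustering import (
    ConsensusResult,
    assign_groups,
    cdf_area,
    consensus_cluster,
    embed,
    gap_statistic,
    hierarchical_cluster,
    kmeans,
    pairwise_dispersion,
    pca_scores,
    select_features,
    select_k,
)
from tests.conftest import make_cohort


def two_clouds(n_per=3, sep=10.0, d=2, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(scale=0.2, size=(n_per, d))
    b = rng.normal(scale=0.2, size=(n_per, d)) + sep
    return np.vstack([a, b])


def three_clouds(n_per=15, sep=8.0, d=5, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, d))
    centers[1, 0] = sep
    centers[2, 1] = sep
    X = np.vstack([rng.normal(size=(n_per, d)) + c for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return X, labels


class TestSelectFeatures:
    def test_top_variance_sites_with_tie_broken_by_position(self):
        # site 0 has variance 0.16, site 2 has 0.01, the rest are constant
        beta = np.full((4, 12), 0.5)
        beta[:, 0] = [0.1, 0.9, 0.1, 0.9]
        beta[:, 2] = [0.3, 0.5, 0.3, 0.5]
        fm = select_features(make_cohort(beta), n_top=2)
        assert list(fm.site_indices) == [0, 2]
        # exact tie between equal-variance sites goes to the earlier site
        beta[:, 7] = [0.3, 0.5, 0.3, 0.5]
        fm = select_features(make_cohort(beta), n_top=2)
        assert list(fm.site_indices) == [0, 2]

    def test_all_constant_matrix_rejected(self):
        cohort = make_cohort(np.full((4, 20), 0.5))
        with pytest.raises(ValueError, match="zero beta variance"):
            select_features(cohort, n_top=5)

    def test_n_top_larger_than_available_warns_and_uses_all(self):
        rng = np.random.default_rng(1)
        cohort = make_cohort(rng.random((4, 20)))
        with pytest.warns(UserWarning, match="usable sites"):
            fm = select_features(cohort, n_top=100)
        assert fm.values.shape == (4, 20)

    def test_sites_masked_anywhere_are_excluded(self):
        rng = np.random.default_rng(2)
        beta = rng.random((4, 20))
        n_total = np.full((4, 20), 30)
        n_total[2, 7] = 2  # below min coverage in one sample
        cohort = make_cohort(beta, n_total=n_total)
        fm = select_features(cohort, n_top=20)
        assert 7 not in fm.site_indices


class TestKmeans:
    def test_two_cloud_split_matches_hand_within_ss(self):
        X = np.array([[0, 0], [0, 1], [1, 0],
                      [10, 10], [10, 11], [11, 10]], dtype=float)
        labels, centers, ss = kmeans(X, 2, seed=0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        # each cloud: mean (1/3, 1/3) offset, total squared deviation 4/3
        assert ss == pytest.approx(8.0 / 3.0, abs=1e-12)

    def test_k_equals_n_gives_zero_dispersion(self):
        X = two_clouds()
        _, _, ss = kmeans(X, X.shape[0], seed=0)
        assert ss == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_labels(self):
        X, _ = three_clouds()
        la, _, _ = kmeans(X, 3, seed=42)
        lb, _, _ = kmeans(X, 3, seed=42)
        assert np.array_equal(la, lb)

    def test_invalid_k_rejected(self):
        X = two_clouds()
        with pytest.raises(ValueError, match="k must be >= 1"):
            kmeans(X, 0)
        with pytest.raises(ValueError, match="exceeds n_samples"):
            kmeans(X, 99)

    def test_gram_reduction_preserves_dispersion(self):
        # more features than samples triggers the exact isometric embedding
        rng = np.random.default_rng(3)
        X = rng.random((8, 200))
        labels, _, ss = kmeans(X, 3, seed=5)
        assert ss == pytest.approx(pairwise_dispersion(X, labels), rel=1e-9)


def test_pairwise_dispersion_equals_within_cluster_ss():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 4))
    labels, centers, ss = kmeans(X, 3, seed=1)
    assert pairwise_dispersion(X, labels) == pytest.approx(ss, rel=1e-9)


class TestConsensus:
    def test_separated_clouds_give_binary_consensus(self):
        X = two_clouds(n_per=5)
        res = consensus_cluster(X, k_range=[2], H=40, p=0.8, seed=0)
        C = res.matrices[2]
        within = np.concatenate([C[:5, :5].ravel(), C[5:, 5:].ravel()])
        assert np.allclose(within, 1.0)
        assert np.allclose(C[:5, 5:], 0.0)

    def test_explicit_subsamples_match_hand_computation(self):
        # 4 points: two tight pairs far apart; k=2 always separates pairs
        X = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        subs = [np.array([0, 1, 2]), np.array([1, 2, 3])]
        res = consensus_cluster(X, k_range=[2], subsamples=subs, seed=0)
        expected = np.array(
            [[1.0, 1.0, 0.0, 0.5],
             [1.0, 1.0, 0.0, 0.0],
             [0.0, 0.0, 1.0, 1.0],
             [0.5, 0.0, 1.0, 1.0]]
        )
        assert np.allclose(res.matrices[2], expected)

    def test_matrices_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(4)
        X = rng.random((12, 6))
        res = consensus_cluster(X, k_range=range(2, 5), H=20, seed=1)
        for k, C in res.matrices.items():
            assert np.allclose(C, C.T)
            assert np.allclose(np.diag(C), 1.0)
            assert C.min() >= 0.0 and C.max() <= 1.0

    def test_small_h_rejected(self):
        with pytest.raises(ValueError, match="H must be >= 2"):
            consensus_cluster(two_clouds(), k_range=[2], H=1)


class TestCdfArea:
    @staticmethod
    def _result_from_entries(entries, n):
        C = np.eye(n)
        iu = np.triu_indices(n, 1)
        C[iu] = entries
        C.T[iu] = entries
        return ConsensusResult(k_range=[2], H=10, p=0.8, matrices={2: C})

    def test_two_point_distribution_closed_form(self):
        # entries in {0, 1} with fraction q at 0 -> area = q
        n = 9  # 36 pairs
        for n_zero in (9, 18, 27):
            entries = np.r_[np.zeros(n_zero), np.ones(36 - n_zero)]
            res = self._result_from_entries(entries, n)
            q = n_zero / 36
            assert cdf_area(res)["area"].iloc[0] == pytest.approx(q, abs=1e-12)

    def test_identical_entries_give_zero_area(self):
        res = self._result_from_entries(np.full(36, 0.7), 9)
        assert cdf_area(res)["area"].iloc[0] == 0.0

    def test_delta_at_first_k_equals_area(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 4))
        res = consensus_cluster(X, k_range=range(2, 5), H=20, seed=2)
        df = cdf_area(res)
        assert df["delta"].iloc[0] == df["area"].iloc[0]
        a = df["area"].to_numpy()
        assert df["delta"].iloc[1] == pytest.approx((a[1] - a[0]) / a[0])

    def test_non_contiguous_k_range_rejected(self):
        res = ConsensusResult(k_range=[2, 4], H=10, p=0.8,
                              matrices={2: np.eye(4), 4: np.eye(4)})
        with pytest.raises(ValueError, match="missing k=3"):
            cdf_area(res)


class TestGapStatistic:
    def test_single_cloud_prefers_one_cluster(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(50, 5))
            res = gap_statistic(X, k_range=range(1, 6), B=30, seed=seed)
            hits += res.k_hat == 1
        assert hits >= 8

    def test_three_separated_clouds_recovered(self):
        hits = 0
        for seed in range(10):
            X, _ = three_clouds(seed=200 + seed)
            res = gap_statistic(X, k_range=range(1, 7), B=30, seed=seed)
            hits += res.k_hat == 3
        assert hits >= 9

    def test_dispersion_decreases_with_k(self):
        X, _ = three_clouds()
        res = gap_statistic(X, k_range=range(1, 7), B=5, seed=0, n_restarts=20)
        W = res.table["W"].to_numpy()
        assert (np.diff(W) <= 1e-9).all()

    def test_small_b_rejected(self):
        with pytest.raises(ValueError, match="B must be >= 2"):
            gap_statistic(two_clouds(), B=1)


class TestHierarchical:
    def test_two_pairs_recovered_at_k2(self):
        X = np.array([[0.0, 0], [0.2, 0], [5, 5], [5.2, 5]])
        labels, order = hierarchical_cluster(X, 2)
        assert labels[0] == labels[1] != labels[2] == labels[3]
        assert sorted(order) == [0, 1, 2, 3]

    def test_k_equals_n_gives_singletons(self):
        X = two_clouds()
        labels, _ = hierarchical_cluster(X, X.shape[0])
        assert len(set(labels)) == X.shape[0]

    def test_agrees_with_kmeans_on_separated_clouds(self):
        X, truth = three_clouds()
        hier, _ = hierarchical_cluster(X, 3)
        km, _, _ = kmeans(X, 3, seed=0)
        assert adjusted_rand_score(hier, km) == 1.0
        assert adjusted_rand_score(hier, truth) == 1.0

    def test_non_finite_rejected(self):
        X = two_clouds().copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            hierarchical_cluster(X, 2)


class TestEmbed:
    def test_pca_exact_on_planar_data(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 6))
        scores = rng.normal(size=(20, 2))
        X = scores @ basis  # lies exactly in a 2-D plane
        coords = embed(X, method="pca")
        # pairwise distances preserved -> reconstruction error 0
        def d2(M):
            return ((M[:, None, :] - M[None]) ** 2).sum(-1)
        assert np.allclose(d2(coords), d2(X - X.mean(0)), atol=1e-8)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-10)

    @pytest.mark.parametrize("method", ["pca", "umap", "tsne"])
    def test_clouds_remain_separated(self, method):
        X, truth = three_clouds()
        coords = embed(X, method=method, seed=0)
        assert coords.shape == (45, 2)
        assert silhouette_score(coords, truth) > 0.5

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown embedding"):
            embed(two_clouds(), method="pcoa")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            embed(np.zeros((2, 4)), method="pca")


class TestSelectK:
    def test_three_cloud_concordance(self):
        X, _ = three_clouds(n_per=10)
        cons = consensus_cluster(X, k_range=range(2, 7), H=50, seed=0)
        gap = gap_statistic(X, k_range=range(1, 7), B=30, seed=0)
        sel = select_k(cons, gap)
        assert sel.k_selected == 3
        assert sel.concordant

    def test_single_cloud_reports_gap_one_and_discord(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        cons = consensus_cluster(X, k_range=range(2, 6), H=40, seed=1)
        gap = gap_statistic(X, k_range=range(1, 6), B=30, seed=1)
        sel = select_k(cons, gap)
        assert sel.k_gap == 1
        assert sel.k_selected >= 2  # primary decision restricted to k >= 2

    def test_deterministic_for_identical_inputs(self):
        X, _ = three_clouds()
        cons = consensus_cluster(X, k_range=range(2, 6), H=30, seed=3)
        gap = gap_statistic(X, k_range=range(1, 6), B=20, seed=3)
        a, b = select_k(cons, gap), select_k(cons, gap)
        assert (a.k_selected, a.k_delta, a.concordant) == \
            (b.k_selected, b.k_delta, b.concordant)
        pd.testing.assert_frame_equal(a.diagnostics, b.diagnostics)

    def test_disjoint_ranges_rejected(self):
        X, _ = three_clouds()
        cons = consensus_cluster(X, k_range=range(2, 4), H=10, seed=0)
        gap = gap_statistic(X, k_range=range(5, 7), B=5, seed=0)
        with pytest.raises(ValueError, match="disjoint"):
            select_k(cons, gap)


class TestAssignGroups:
    def test_k1_gives_all_ones(self):
        assert (assign_groups(two_clouds(), 1) == 1).all()

    def test_groups_numbered_by_descending_size(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(size=(8, 3)),
                       rng.normal(size=(4, 3)) + 20])
        labels = assign_groups(X, 2, seed=0)
        assert (labels[:8] == 1).all() and (labels[8:] == 2).all()

    def test_partition_invariant_to_row_order(self):
        X, _ = three_clouds()
        rng = np.random.default_rng(1)
        perm = rng.permutation(X.shape[0])
        a = assign_groups(X, 3, seed=2)
        b = assign_groups(X[perm], 3, seed=2)
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds n_samples"):
            assign_groups(two_clouds(), 99)


def test_pca_scores_preserve_geometry_when_full_rank():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 5))
    Z = pca_scores(X, 5)
    def d2(M):
        return ((M[:, None, :] - M[None]) ** 2).sum(-1)
    assert np.allclose(d2(Z), d2(X), atol=1e-8)
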