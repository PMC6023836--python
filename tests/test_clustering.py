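import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from devmir.clustering import (
    cluster_overlap_table,
    dmin_curve,
    fuzzy_cmeans,
    order_clusters,
    standardize_profiles,
)


def _planted_profiles(n_per_arch, noise_sd, seed, n_stages=12):
    """Three well-separated temporal shapes plus noise, standardized."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_stages)
    shapes = [2 - 4 * t, 4 * t - 2, 3 * np.exp(-((t - 0.4) ** 2) / 0.02)]
    rows, labels = [], []
    for k, shape in enumerate(shapes):
        for _ in range(n_per_arch):
            rows.append(shape + rng.normal(0, noise_sd, n_stages))
            labels.append(k)
    frame = pd.DataFrame(
        rows, index=[f"f{i}" for i in range(len(rows))],
        columns=[f"s{j}" for j in range(n_stages)],
    )
    standardized, _ = standardize_profiles(frame)
    return standardized, np.array(labels)


class TestStandardize:
    def test_hand_arithmetic_population_sd(self):
        frame = pd.DataFrame([[2.0, 4.0, 6.0]], index=["f"], columns=list("abc"))
        out, excluded = standardize_profiles(frame)
        np.testing.assert_allclose(
            out.loc["f"], [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )
        assert excluded == []

    def test_constant_profile_excluded(self):
        frame = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["const", "ramp"], columns=list("abc")
        )
        out, excluded = standardize_profiles(frame)
        assert excluded == ["const"]
        assert list(out.index) == ["ramp"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(5, 12)))
        once, _ = standardize_profiles(frame)
        twice, _ = standardize_profiles(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_all_constant_errors(self):
        frame = pd.DataFrame([[2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="constant"):
            standardize_profiles(frame)


class TestFuzzyCMeans:
    def test_single_cluster_closed_form(self):
        x, _ = _planted_profiles(10, 0.3, seed=1)
        model = fuzzy_cmeans(x, c=1, seed=0)
        np.testing.assert_allclose(model.membership.to_numpy(), 1.0)
        np.testing.assert_allclose(
            model.centroids.iloc[0], x.mean(axis=0), atol=1e-8
        )

    def test_coincident_point_gets_full_membership(self):
        # a point exactly at a centroid: membership 1 there, 0 elsewhere
        x = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [4.0, 4.0], [4.0, 4.0]],
            index=list("abcd"), columns=["s0", "s1"],
        )
        model = fuzzy_cmeans(x, c=2, seed=0, restarts=3)
        u = model.membership.to_numpy()
        assert np.all(np.max(u, axis=1) == 1.0)

    def test_planted_two_archetype_recovery(self):
        x, labels = _planted_profiles(25, 0.2, seed=3)
        x = x.iloc[:50]  # two shapes only
        model = fuzzy_cmeans(x, c=2, seed=4)
        ari = adjusted_rand_score(labels[:50], model.hard_labels().to_numpy())
        assert ari == 1.0

    def test_membership_rows_sum_to_one(self):
        x, _ = _planted_profiles(20, 0.5, seed=5)
        model = fuzzy_cmeans(x, c=4, seed=6)
        np.testing.assert_allclose(model.membership.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_non_increasing(self):
        x, _ = _planted_profiles(20, 0.4, seed=7)
        for seed in range(5):
            model = fuzzy_cmeans(x, c=3, seed=seed, restarts=1)
            hist = np.array(model.objective_history)
            assert np.all(np.diff(hist) <= 1e-9)

    def test_order_equivariance(self):
        x, _ = _planted_profiles(10, 0.3, seed=8)
        perm = np.random.default_rng(0).permutation(len(x))
        model = fuzzy_cmeans(x, c=3, seed=9)
        model_perm = fuzzy_cmeans(x.iloc[perm], c=3, seed=9)
        # same data, same seed: memberships agree per feature after aligning
        # columns by centroid distance
        from scipy.spatial.distance import cdist

        mapping = np.argmin(
            cdist(model_perm.centroids.to_numpy(), model.centroids.to_numpy()), axis=1
        )
        assert sorted(mapping) == [0, 1, 2]
        aligned = model_perm.membership.to_numpy()[:, np.argsort(mapping)]
        np.testing.assert_allclose(
            aligned,
            model.membership.loc[model_perm.feature_ids].to_numpy(),
            atol=1e-6,
        )

    def test_too_many_clusters_rejected(self):
        x, _ = _planted_profiles(2, 0.1, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            fuzzy_cmeans(x, c=10)

    def test_planted_three_archetype_ari(self):
        # 150 features, noise 0.2, c=3: near-perfect recovery over 10 seeds
        for seed in range(10):
            x, labels = _planted_profiles(50, 0.2, seed=100 + seed)
            model = fuzzy_cmeans(x, c=3, seed=seed)
            ari = adjusted_rand_score(labels, model.hard_labels().to_numpy())
            assert ari >= 0.9


class TestDminCurve:
    def test_separated_archetypes_drop_after_three(self):
        x, _ = _planted_profiles(30, 0.15, seed=11)
        curve = dmin_curve(x, c_range=[2, 3, 4, 5], seed=1).set_index("c")["dmin"]
        assert curve[3] > 2 * curve[4]

    def test_duplicated_rows_near_zero(self):
        row = np.linspace(-1, 1, 12)
        x = pd.DataFrame([row] * 12, index=[f"f{i}" for i in range(12)])
        curve = dmin_curve(x, c_range=[2, 3], seed=0)
        assert (curve["dmin"] < 1e-6).all()

    def test_single_point_curve(self):
        x, _ = _planted_profiles(10, 0.3, seed=12)
        curve = dmin_curve(x, c_range=[2], seed=0)
        assert list(curve["c"]) == [2]


class TestOrderClusters:
    def test_downward_trend_first(self):
        x, labels = _planted_profiles(20, 0.1, seed=13)
        model = order_clusters(fuzzy_cmeans(x, c=3, seed=3))
        trends = model.centroids.iloc[:, -1] - model.centroids.iloc[:, 0]
        assert list(trends) == sorted(trends)

    def test_single_cluster_unchanged(self):
        x, _ = _planted_profiles(5, 0.2, seed=14)
        model = fuzzy_cmeans(x, c=1, seed=0)
        ordered = order_clusters(model)
        pd.testing.assert_frame_equal(model.centroids, ordered.centroids)

    def test_tie_broken_by_lower_mean(self):
        from devmir.clustering import ClusterModel

        centroids = pd.DataFrame([[1.0, 2.0, 1.0], [0.0, 1.0, 0.0]])
        membership = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]], index=["a", "b"], columns=[0, 1]
        )
        model = ClusterModel(membership, centroids, 2.0, 0.0, [], 0, 1)
        ordered = order_clusters(model)
        assert ordered.centroids.iloc[0].mean() < ordered.centroids.iloc[1].mean()


class TestClusterOverlap:
    def test_identical_models_diagonal(self):
        x, _ = _planted_profiles(20, 0.2, seed=15)
        model = fuzzy_cmeans(x, c=3, seed=5)
        table, unmatched = cluster_overlap_table(model, model)
        off_diag = table.to_numpy().sum() - np.trace(table.to_numpy())
        assert off_diag == 0
        assert unmatched["only_in_a"] == [] and unmatched["only_in_b"] == []

    def test_disjoint_feature_sets(self):
        x, _ = _planted_profiles(10, 0.2, seed=16)
        a = fuzzy_cmeans(x.iloc[:15], c=2, seed=1)
        b = fuzzy_cmeans(x.iloc[15:], c=2, seed=1)
        table, unmatched = cluster_overlap_table(a, b)
        assert table.to_numpy().sum() == 0
        assert len(unmatched["only_in_a"]) == 15

    def test_manual_tally(self):
        from devmir.clustering import ClusterModel

        def tiny_model(labels):
            ids = list(labels)
            u = pd.DataFrame(0.0, index=ids, columns=[0, 1])
            for fid, lab in labels.items():
                u.loc[fid, lab] = 1.0
            centroids = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]])
            return ClusterModel(u, centroids, 2.0, 0.0, [], 0, 1)

        a = tiny_model({"f1": 0, "f2": 0, "f3": 1, "f4": 1, "f5": 1})
        b = tiny_model({"f1": 0, "f2": 1, "f3": 1, "f4": 1, "f6": 0})
        table, unmatched = cluster_overlap_table(a, b)
        assert table.loc[0, 0] == 1  # f1
        assert table.loc[0, 1] == 1  # f2
        assert table.loc[1, 1] == 2  # f3, f4
        assert unmatched["only_in_a"] == ["f5"]
        assert unmatched["only_in_b"] == ["f6"]
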