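import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenosig.classify import (choose_period, davies_bouldin, export_dendrogram,
                               hcluster, loo_bootstrap, misclassification_count)
from phenosig.exceptions import ParameterError, ValidationError
from phenosig.wavelet_sig import default_period_grid, wavelet_transform


def naive_davies_bouldin(X, labels):
    """Independent from-definition reimplementation used as an oracle."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    cents, scatters = [], []
    for u in uniq:
        pts = X[labels == u]
        c = pts.mean(axis=0)
        cents.append(c)
        scatters.append(np.mean([np.sqrt(((p - c) ** 2).sum()) for p in pts]))
    total = 0.0
    for i in range(len(uniq)):
        worst = 0.0
        for j in range(len(uniq)):
            if i == j:
                continue
            m = np.sqrt(((cents[i] - cents[j]) ** 2).sum())
            worst = max(worst, (scatters[i] + scatters[j]) / m if m else np.inf)
        total += worst
    return total / len(uniq)


class TestHCluster:
    def test_duplicated_triplicates_recover_groups(self):
        X = np.vstack([np.tile([0.0, 0.0], (3, 1)), np.tile([9.0, 9.0], (3, 1))])
        res = hcluster(X, 2, true_groups=[0, 0, 0, 1, 1, 1])
        assert res.n_misclassified == 0
        # zero-distance duplicates merge at height 0
        assert res.linkage[0, 2] == 0.0

    def test_line_points_average_linkage(self):
        # average linkage on {0, 1, 10, 11}: the two tight pairs merge first
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        res = hcluster(X, 2)
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]

    def test_k_one_is_a_single_cluster(self):
        res = hcluster(np.random.default_rng(0).normal(size=(5, 2)), 1)
        assert len(np.unique(res.labels)) == 1
        assert np.isnan(res.db_score)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ParameterError):
            hcluster(np.zeros((3, 2)), 4)

    def test_order_invariance_up_to_renaming(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.1, (4, 3)), rng.normal(5, 0.1, (4, 3))])
        groups = np.array([0] * 4 + [1] * 4)
        perm = rng.permutation(8)
        a = hcluster(X, 2).labels
        b = hcluster(X[perm], 2).labels
        assert misclassification_count(b, a[perm]) == 0


class TestDaviesBouldin:
    def test_two_singletons_score_zero(self):
        assert davies_bouldin([[0.0, 0], [5.0, 5]], [0, 1]) == 0.0

    def test_hand_case(self):
        X = [[0, 0], [0, 2], [10, 0], [10, 2]]
        assert davies_bouldin(X, [0, 0, 1, 1]) == pytest.approx(0.2)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        labels = rng.integers(0, 3, 12)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, 12)
        s1 = davies_bouldin(X, labels)
        s2 = davies_bouldin(X + 7.3, labels)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_coincident_centroids_give_inf(self):
        X = np.array([[0.0, 0], [2, 0], [0, 0], [2, 0]])
        assert davies_bouldin(X, [0, 0, 1, 1]) == np.inf

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 3))
        labels = rng.integers(0, 4, 20)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert davies_bouldin(X, labels) == pytest.approx(
            naive_davies_bouldin(X, labels), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import davies_bouldin_score

        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, 30)
        assert davies_bouldin(X, labels) == pytest.approx(
            davies_bouldin_score(X, labels), rel=1e-9
        )


class TestChoosePeriod:
    DT = 1 / 6

    def test_period_24_component_is_selected(self):
        t = np.arange(0, 60, self.DT)
        rng = np.random.default_rng(0)
        periods = default_period_grid(self.DT, 60.0)
        sigs, groups = [], []
        base = 0.3 * np.sin(2 * np.pi * t / 7.0)
        for g in range(2):
            for _ in range(3):
                x = base + 0.02 * rng.standard_normal(len(t))
                if g == 0:
                    x = x + 0.5 * np.sin(2 * np.pi * t / 24.0)
                sigs.append(wavelet_transform(x, dt=self.DT, periods=periods))
                groups.append(g)
        p, scores = choose_period(sigs, groups)
        step = periods[1] / periods[0]
        assert 1 / step <= p / 24.0 <= step
        assert scores[np.argmin(scores)] == min(scores)

    def test_identical_groups_score_inf_and_fall_back(self, caplog):
        sigs = [wavelet_transform(np.zeros(64), dt=self.DT) for _ in range(4)]
        with caplog.at_level("WARNING"):
            p, scores = choose_period(sigs, [0, 0, 1, 1])
        assert np.all(np.isinf(scores))
        assert p == sigs[0].periods[0]

    def test_exclusion_mask_is_honored(self):
        rng = np.random.default_rng(1)
        sigs = [wavelet_transform(rng.standard_normal(64), dt=self.DT)
                for _ in range(4)]
        mask = np.zeros(len(sigs[0].periods), dtype=bool)
        p_free, scores_free = choose_period(sigs, [0, 0, 1, 1])
        mask[np.argmin(scores_free)] = True
        p_masked, _ = choose_period(sigs, [0, 0, 1, 1], exclude_mask=mask)
        assert p_masked != p_free


class TestLeaveOneOut:
    def test_separated_groups_all_zero(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(i * 10, 0.1, (3, 2)) for i in range(3)])
        groups = np.repeat(np.arange(3), 3)
        counts = loo_bootstrap(X, groups, 3)
        assert counts.shape == (9,)
        assert np.all(counts == 0)

    def test_overlapping_groups_misclassify(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1.0, (10, 2))  # two "groups" from one distribution
        groups = np.repeat([0, 1], 5)
        counts = loo_bootstrap(X, groups, 2)
        assert counts.sum() > 0

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            loo_bootstrap(np.zeros((3, 2)), [0, 0, 1], 2)


class TestMisclassification:
    def test_renamed_labels_count_zero(self):
        true = [0, 0, 1, 1, 2, 2]
        pred = [5, 5, 9, 9, 7, 7]
        assert misclassification_count(pred, true) == 0

    def test_single_moved_sample(self):
        true = [0, 0, 0, 1, 1, 1]
        pred = [0, 0, 1, 1, 1, 1]
        assert misclassification_count(pred, true) == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=8, max_size=12))
    def test_matches_permutation_oracle(self, pred):
        rng = np.random.default_rng(len(pred))
        true = rng.integers(0, 4, len(pred))
        # brute force over all assignments of predicted labels to true labels
        pl = sorted(set(pred))
        tl = sorted(set(true.tolist()))
        k = max(len(pl), len(tl))
        best = len(pred)
        for perm in itertools.permutations(range(k), len(pl)):
            correct = sum(
                1 for p, t in zip(pred, true)
                if perm[pl.index(p)] < len(tl) and tl[perm[pl.index(p)]] == t
            )
            best = min(best, len(pred) - correct)
        assert misclassification_count(pred, true) == best


class TestNewickExport:
    def test_two_leaves(self):
        X = np.array([[0.0], [4.0]])
        res = hcluster(X, 2, names=["A", "B"])
        assert export_dendrogram(res) == "(A:2,B:2);"

    def test_three_leaf_hand_case(self):
        # points 0, 1, 5: (0,1) merge at height 1; then average linkage joins
        # 5 at height (5-0 + 5-1)/2 = 4.5
        X = np.array([[0.0], [1.0], [5.0]])
        res = hcluster(X, 1, names=["a", "b", "c"])
        assert export_dendrogram(res) in (
            "((a:0.5,b:0.5):1.75,c:2.25);",
            "(c:2.25,(a:0.5,b:0.5):1.75);",
        )

    def test_round_trip_topology(self, default_panel):
        import io

        import skbio

        from phenosig.workflows import signature_study

        study = signature_study(default_panel)
        nwk = export_dendrogram(study.clustering)
        tree = skbio.TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == set(study.clustering.names)
        # cophenetic distance between the first two leaves matches the tree
        names = study.clustering.names
        a, b = names[0], names[1]
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        coph = squareform(cophenet(study.clustering.linkage))
        assert tree.find(a).distance(tree.find(b)) == pytest.approx(
            coph[0, 1], rel=1e-6
        )
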