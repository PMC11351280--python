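"""Gini node impurity, forest importance accumulation, and longitudinal profiles."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

import tcpca
from conftest import make_cohort
from tcpca.importance import forest_gini_importance, node_gini


class TestNodeGini:
    @pytest.mark.parametrize(
        "proportions,expected",
        [
            ((1.0, 0.0), 0.0),
            ((0.5, 0.5), 0.5),
            ((0.2, 0.3, 0.5), 1.0 - (0.04 + 0.09 + 0.25)),
        ],
    )
    def test_known_values(self, proportions, expected):
        assert node_gini(proportions) == pytest.approx(expected, abs=1e-12)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            node_gini([0.5, 0.6])
        with pytest.raises(ValueError):
            node_gini([-0.1, 1.1])


def recursive_traversal_oracle(tree, n_features, weighted=False):
    """Independent recursive accumulation of per-split impurity changes."""
    counts = tree.value[:, 0, :]
    props = counts / counts.sum(axis=1, keepdims=True)
    gini = 1.0 - (props**2).sum(axis=1)
    scores = np.zeros(n_features)

    def visit(node):
        left, right = tree.children_left[node], tree.children_right[node]
        if left < 0:
            return
        if weighted:
            w = tree.weighted_n_node_samples
            change = gini[node] - (
                w[left] * gini[left] + w[right] * gini[right]
            ) / w[node]
        else:
            change = gini[node] - gini[left] - gini[right]
        scores[tree.feature[node]] += change
        visit(left)
        visit(right)

    visit(0)
    return scores


class TestForestGiniImportance:
    def test_perfect_stump_scores_one_half(self, rng_factory):
        rng = rng_factory(0)
        x = np.zeros((40, 3))
        y = np.repeat([0, 1], 20)
        x[:, 1] = y * 2.0 - 1.0  # feature 1 separates perfectly
        x += 0.01 * rng.normal(size=x.shape)
        stump = RandomForestClassifier(
            n_estimators=1, max_depth=1, bootstrap=False, max_features=None,
            random_state=0,
        ).fit(x, y)
        imp = forest_gini_importance(stump, 3, normalize=False)
        np.testing.assert_allclose(imp.scores, [0.0, 0.5, 0.0], atol=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_recursive_traversal_oracle(self, weighted, rng_factory):
        rng = rng_factory(1)
        x = rng.normal(size=(150, 6))
        y = (x[:, 0] + 0.5 * x[:, 3] > 0).astype(int) + (x[:, 5] > 1).astype(int)
        forest = RandomForestClassifier(n_estimators=15, random_state=0).fit(x, y)
        imp = forest_gini_importance(forest, 6, normalize=False, weighted=weighted)
        expected = np.zeros(6)
        for est in forest.estimators_:
            expected += recursive_traversal_oracle(est.tree_, 6, weighted)
        np.testing.assert_allclose(imp.scores, expected, atol=1e-12)

    def test_normalized_scores_sum_to_one(self, rng_factory):
        rng = rng_factory(2)
        x = rng.normal(size=(100, 5))
        y = (x[:, 2] > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=10, random_state=1).fit(x, y)
        imp = forest_gini_importance(forest, 5, normalize=True)
        assert imp.scores.sum() == pytest.approx(1.0, abs=1e-12)
        assert imp.normalized

    def test_feature_relabeling_permutes_scores(self):
        # accumulation must depend only on tree structure and split-feature ids:
        # relabeling the ids of an otherwise identical tree permutes the scores

        class _Tree:
            def __init__(self, feature):
                self.children_left = np.array([1, -1, -1])
                self.children_right = np.array([2, -1, -1])
                self.feature = np.array([feature, -2, -2])
                self.value = np.array([[[10.0, 10.0]], [[9.0, 1.0]], [[1.0, 9.0]]])
                self.weighted_n_node_samples = np.array([20.0, 10.0, 10.0])

        class _Forest:
            def __init__(self, features):
                self.estimators_ = [
                    type("E", (), {"tree_": _Tree(f)})() for f in features
                ]

        s1 = forest_gini_importance(_Forest([0, 2]), 4, normalize=False).scores
        s2 = forest_gini_importance(_Forest([3, 1]), 4, normalize=False).scores
        perm = np.array([3, 2, 1, 0])  # relabel j -> 3 - j
        np.testing.assert_allclose(s1, s2[perm], atol=1e-12)

    def test_unweighted_rule_telescopes_on_single_path_trees(self, rng_factory):
        # depth-limited stump chain on one feature: accumulated changes equal
        # root gini minus the sum of leaf ginis
        rng = rng_factory(4)
        x = rng.uniform(size=(64, 1))
        y = (x[:, 0] > 0.5).astype(int)
        tree = DecisionTreeClassifier(max_leaf_nodes=4, random_state=0).fit(x, y)

        class _One:
            estimators_ = [tree]

        imp = forest_gini_importance(_One(), 1, normalize=False)
        t = tree.tree_
        counts = t.value[:, 0, :]
        props = counts / counts.sum(axis=1, keepdims=True)
        gini = 1.0 - (props**2).sum(axis=1)
        leaves = t.children_left < 0
        # every split is on feature 0; each non-root internal node appears once
        # as parent (+) and once as child (-), so the sum telescopes to the
        # root impurity minus the summed leaf impurities
        expected = gini[0] - gini[leaves].sum()
        assert imp.scores[0] == pytest.approx(expected, abs=1e-12)

    def test_unfitted_forest_rejected(self):
        with pytest.raises(ValueError, match="fitted"):
            forest_gini_importance(RandomForestClassifier(), 3)


class TestRepresentativeFeatures:
    def _imp(self, scores):
        return tcpca.GiniImportance(
            scores=np.asarray(scores), normalized=True, n_trees=10, class_count=2
        )

    def test_threshold_is_strict(self):
        out = tcpca.representative_features(self._imp([0.5, 0.3, 0.15, 0.03, 0.02]))
        assert [name for name, _ in out] == [0, 1, 2, 3]  # 0.02 excluded

    def test_all_below_threshold_gives_empty_list(self):
        assert tcpca.representative_features(self._imp([0.5, 0.5]), threshold=0.6) == []

    def test_zero_threshold_keeps_positive_scores(self):
        out = tcpca.representative_features(self._imp([0.7, 0.3, 0.0]), threshold=0.0)
        assert [name for name, _ in out] == [0, 1]

    def test_unnormalized_input_rejected(self):
        imp = tcpca.GiniImportance(
            scores=np.array([2.0, 1.0]), normalized=False, n_trees=1, class_count=2
        )
        with pytest.raises(ValueError, match="normalized"):
            tcpca.representative_features(imp)


class TestLongitudinalImportance:
    FOREST = {"n_estimators": 60}

    def test_planted_visit_signal_localized(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            values = rng.normal(size=(150, 4, 8))
            y = (values[:, 2, 5] > 0).astype(int)  # visit 2, feature 5 drives labels
            li = tcpca.longitudinal_importance(
                make_cohort(values), y, self.FOREST, seed=seed
            )
            if int(np.argmax(li.matrix[2])) == 5:
                hits += 1
        assert hits >= n_seeds - 1

    def test_rows_sum_to_one(self, rng_factory):
        rng = rng_factory(5)
        values = rng.normal(size=(80, 3, 5))
        y = (values[:, 0, 0] > 0).astype(int)
        li = tcpca.longitudinal_importance(make_cohort(values), y, self.FOREST)
        np.testing.assert_allclose(li.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_permuted_labels_show_no_concentration(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(120, 2, 10))
        y = (values[:, 1, 3] > 0).astype(int)
        y_perm = rng.permutation(y)
        li = tcpca.longitudinal_importance(
            make_cohort(values), y_perm, self.FOREST, seed=0
        )
        top = li.matrix[1].max()
        null_tops = []
        for s in range(12):
            li0 = tcpca.longitudinal_importance(
                make_cohort(values), rng.permutation(y), self.FOREST, seed=s
            )
            null_tops.append(li0.matrix[1].max())
        z = (top - np.mean(null_tops)) / np.std(null_tops)
        assert z < 3.0

    def test_single_class_labels_rejected(self, rng_factory):
        rng = rng_factory(7)
        values = rng.normal(size=(20, 2, 3))
        with pytest.raises(ValueError, match="two classes"):
            tcpca.longitudinal_importance(make_cohort(values), np.zeros(20))
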