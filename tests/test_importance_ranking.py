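import numpy as np
import pytest

from regmodules.dataio import ContextLabels, preprocess_expression
from regmodules.importance_ranking import (
    DOWN,
    UP,
    ForestModel,
    TreeNode,
    delta_gini,
    feature_importance,
    gini,
    module_status,
    rank_modules,
    train_ovr_forest,
)
from regmodules.ssgsea import RMESMatrix, SsgseaParams, build_rmes


def leaf(counts):
    counts = np.asarray(counts, dtype=float)
    return TreeNode(n_samples=counts.sum(), class_probs=counts / counts.sum())


def split(counts, feature, left, right, threshold=0.0):
    counts = np.asarray(counts, dtype=float)
    return TreeNode(n_samples=counts.sum(), class_probs=counts / counts.sum(),
                    feature=feature, threshold=threshold, left=left, right=right)


def random_tree(rng, counts, features, depth=0):
    """Random class-count-consistent binary tree for oracle checks."""
    counts = np.asarray(counts, dtype=int)
    if counts.sum() < 2 or depth >= 4 or rng.random() < 0.3:
        return leaf(np.maximum(counts, 1e-12))
    left = np.array([int(rng.integers(0, c + 1)) for c in counts])
    if left.sum() == 0 or (counts - left).sum() == 0:
        return leaf(np.maximum(counts, 1e-12))
    return split(np.maximum(counts, 1e-12), str(rng.choice(features)),
                 random_tree(rng, left, features, depth + 1),
                 random_tree(rng, counts - left, features, depth + 1))


def fis_per_feature_scan(forest: ForestModel) -> dict[str, float]:
    """Independent accumulation: flatten every tree to node records, then
    scan once per feature, recomputing the impurity drop from raw
    child/parent distributions rather than via delta_gini."""
    records = []
    for t_idx, root in enumerate(forest.trees):
        queue = [root]
        while queue:
            node = queue.pop(0)
            if node.feature is None:
                continue
            g = lambda p: 1.0 - float(np.sum(np.asarray(p) ** 2))
            drop = (
                g(node.class_probs)
                - node.left.n_samples / node.n_samples * g(node.left.class_probs)
                - node.right.n_samples / node.n_samples * g(node.right.class_probs)
            )
            records.append((t_idx, node.feature, node.n_samples, drop))
            queue.extend([node.left, node.right])
    out = {}
    for m in forest.feature_ids:
        total = sum(
            s_n / forest.n_train_samples * drop
            for _, feat, s_n, drop in records
            if feat == m
        )
        out[m] = total / len(forest.trees)
    return out


class TestGini:
    @pytest.mark.parametrize("probs,expected", [
        ((1.0, 0.0), 0.0),
        ((0.5, 0.5), 0.5),
        ((0.9, 0.1), 0.18),
    ])
    def test_values(self, probs, expected):
        assert gini(probs) == pytest.approx(expected)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            gini((0.5, 0.4))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            gini((1.2, -0.2))


class TestDeltaGini:
    def test_pure_split_of_balanced_node(self):
        node = split([5, 5], "m", leaf([5, 1e-12]), leaf([1e-12, 5]))
        assert delta_gini(node) == pytest.approx(0.5, abs=1e-9)

    def test_uninformative_split_is_zero(self):
        node = split([8, 2], "m", leaf([4, 1]), leaf([4, 1]))
        assert delta_gini(node) == pytest.approx(0.0, abs=1e-12)

    def test_leaf_rejected(self):
        with pytest.raises(ValueError):
            delta_gini(leaf([3, 3]))


class TestFeatureImportance:
    def test_single_stump_pure_split(self):
        stump = split([5, 5], "m1", leaf([5, 1e-12]), leaf([1e-12, 5]))
        forest = ForestModel(trees=[stump], n_train_samples=10,
                             feature_ids=["m1", "m2"], context="c")
        fis = feature_importance(forest)
        assert fis["m1"] == pytest.approx(0.5, abs=1e-9)
        assert fis["m2"] == 0.0

    def test_all_leaf_forest_is_zero(self):
        forest = ForestModel(trees=[leaf([3, 2]), leaf([2, 3])],
                             n_train_samples=5, feature_ids=["m1"], context="c")
        assert feature_importance(forest) == {"m1": 0.0}

    def test_duplicating_trees_leaves_fis_unchanged(self):
        rng = np.random.default_rng(0)
        trees = [random_tree(rng, [6, 4], ["a", "b"]) for _ in range(3)]
        f1 = ForestModel(trees=trees, n_train_samples=10,
                         feature_ids=["a", "b"], context="c")
        f2 = ForestModel(trees=trees * 2, n_train_samples=10,
                         feature_ids=["a", "b"], context="c")
        a, b = feature_importance(f1), feature_importance(f2)
        for m in ("a", "b"):
            assert a[m] == pytest.approx(b[m], abs=1e-12)

    def test_matches_per_feature_scan_oracle_on_random_forests(self):
        """50 random small forests: per-node traversal == per-feature scan
        to 1e-12."""
        rng = np.random.default_rng(99)
        features = ["m1", "m2", "m3", "m4"]
        for _ in range(50):
            trees = [
                random_tree(rng, rng.integers(1, 12, size=3), features)
                for _ in range(int(rng.integers(1, 6)))
            ]
            forest = ForestModel(
                trees=trees,
                n_train_samples=int(rng.integers(5, 40)),
                feature_ids=features,
                context="c",
            )
            mine = feature_importance(forest)
            oracle = fis_per_feature_scan(forest)
            for m in features:
                assert mine[m] == pytest.approx(oracle[m], abs=1e-12)


def _separable_rmes(n=60, seed=0):
    """One informative column among 5; positives shifted by +2."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n, 5)) * 0.1
    y = np.array([i < n // 3 for i in range(n)])
    scores[y, 2] += 2.0
    samples = [f"s{i}" for i in range(n)]
    rmes = RMESMatrix(sample_ids=samples,
                      module_ids=[f"M{j}(+)" for j in range(5)], scores=scores)
    labels = ContextLabels(
        {s: ("pos" if flag else "neg") for s, flag in zip(samples, y)}
    )
    return rmes, labels


class TestTrainOvrForest:
    def test_informative_feature_attains_max_fis(self):
        rmes, labels = _separable_rmes()
        forest = train_ovr_forest(rmes, labels, "pos", n_trees=100, seed=1)
        fis = feature_importance(forest)
        assert max(fis, key=fis.get) == "M2(+)"

    def test_unknown_context_rejected(self):
        rmes, labels = _separable_rmes()
        with pytest.raises(ValueError):
            train_ovr_forest(rmes, labels, "nope", n_trees=10, seed=0)

    def test_single_class_rejected(self):
        # the only "other"-context sample is absent from the matrix, so the
        # aligned label vector is single-class
        rmes, _ = _separable_rmes()
        assignments = {s: "only" for s in rmes.sample_ids}
        assignments["absent_sample"] = "other"
        labels = ContextLabels(assignments)
        with pytest.raises(ValueError):
            train_ovr_forest(rmes, labels, "only", n_trees=10, seed=0)

    def test_deterministic_given_seed(self):
        rmes, labels = _separable_rmes()
        a = feature_importance(train_ovr_forest(rmes, labels, "pos", 50, seed=3))
        b = feature_importance(train_ovr_forest(rmes, labels, "pos", 50, seed=3))
        assert a == b


class TestModuleStatus:
    def test_higher_positive_mean_is_up(self):
        rmes, labels = _separable_rmes()
        assert module_status(rmes, labels, "pos", "M2(+)") == UP

    def test_negating_column_flips_status(self):
        rmes, labels = _separable_rmes()
        flipped = RMESMatrix(sample_ids=rmes.sample_ids,
                             module_ids=rmes.module_ids, scores=-rmes.scores)
        assert module_status(flipped, labels, "pos", "M2(+)") == DOWN

    def test_equal_means_map_to_down(self):
        rmes = RMESMatrix(sample_ids=["a", "b"], module_ids=["M(+)"],
                          scores=np.array([[0.3], [0.3]]))
        labels = ContextLabels({"a": "x", "b": "y"})
        assert module_status(rmes, labels, "x", "M(+)") == DOWN


class TestRankModules:
    def test_planted_modules_rank_first(self, small_cohort, small_cohort_modules):
        """Scoring the true gene sets on a synthetic cohort puts each
        context's planted modules at the top of its table."""
        cfg, expr_raw, labels, truth = small_cohort
        expr = preprocess_expression(expr_raw)
        rmes = build_rmes(expr, small_cohort_modules, SsgseaParams())
        tables = rank_modules(rmes, labels, n_trees=100, seed=5)
        for context in labels.contexts:
            planted = set(truth.planted_in(context))
            top = set(tables[context].head(len(planted)).module_id)
            assert top == planted
            for mid in planted:
                row = tables[context].set_index("module_id").loc[mid]
                direction = truth.context_assignments[mid][1]
                assert row.status == (UP if direction == "up" else DOWN)

    def test_top_n_truncates(self, small_cohort, small_cohort_modules):
        cfg, expr_raw, labels, truth = small_cohort
        expr = preprocess_expression(expr_raw)
        rmes = build_rmes(expr, small_cohort_modules, SsgseaParams())
        tables = rank_modules(rmes, labels, n_trees=20, seed=0, top_n=0)
        assert all(t.empty for t in tables.values())

    def test_ranks_sorted_by_fis_with_id_tiebreak(self):
        rmes, labels = _separable_rmes()
        tables = rank_modules(rmes, labels, n_trees=50, seed=2)
        t = tables["pos"]
        assert list(t["rank"]) == list(range(1, len(t) + 1))
        fis = list(t.fis)
        assert fis == sorted(fis, reverse=True)
        zero = t[t.fis == 0]
        assert list(zero.module_id) == sorted(zero.module_id)
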