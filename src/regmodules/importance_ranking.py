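"""Per-context module ranking by one-vs-rest random-forest Gini importance.

For each context c, a binary random forest is trained with the RMES
columns as features: samples labeled c are positives, all other labeled
samples negatives. The importance of module m is its mean-decrease-
impurity feature importance score,

    FIS(m) = (1/T) * sum_t sum_{nodes n in tree t with f(n)=m}
             (S_n / S) * dGini(n)

    dGini(n) = Gini(n) - (S_left/S_n) Gini(left) - (S_right/S_n) Gini(right)
    Gini(n)  = 1 - sum_c p(c|n)^2

where T is the number of trees, S the per-tree training-sample count, and
S_n the (bootstrap-weighted) sample count at node n. FIS is taken
literally — not re-normalized across features — so absolute values are
comparable across contexts of one run. The forest fitting itself is
delegated to scikit-learn; fitted trees are extracted into an explicit
node structure and the importance accumulation above is computed here.

Each top module is labeled up-regulated when its mean enrichment is
higher in the positive samples than in the negatives, else down-regulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .dataio import ContextLabels
from .ssgsea import RMESMatrix

UP = "up_regulated"
DOWN = "down_regulated"

DEFAULT_N_TREES = 500  # forest size used throughout: 500 Gini trees


@dataclass
class TreeNode:
    """One node of a fitted decision tree.

    Internal nodes carry the splitting feature (a module_id) and a
    threshold; leaves have ``feature=None``. ``n_samples`` is the
    (bootstrap-weighted) training-sample count reaching the node and
    ``class_probs`` the class distribution among them.
    """

    n_samples: float
    class_probs: np.ndarray
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    def __post_init__(self) -> None:
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        if (self.left is None) != (self.right is None):
            raise ValueError("node must have zero or two children")
        if (self.feature is None) != (self.left is None):
            raise ValueError("feature must be set exactly on internal nodes")

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class ForestModel:
    """A fitted one-vs-rest forest: T tree roots plus training metadata."""

    trees: list[TreeNode]
    n_train_samples: int
    feature_ids: list[str]
    context: str

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("forest must contain at least one tree")
        if self.n_train_samples < 1:
            raise ValueError("n_train_samples must be positive")


def gini(class_probs: Sequence[float]) -> float:
    """Gini impurity 1 - sum(p^2) of a class-probability vector."""
    p = np.asarray(class_probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("class probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class probabilities sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p**2))


def delta_gini(node: TreeNode) -> float:
    """Impurity decrease of one split: parent Gini minus the
    child-sample-weighted child Ginis."""
    if node.is_leaf:
        raise ValueError("delta_gini is undefined for a leaf node")
    assert node.left is not None and node.right is not None
    return (
        gini(node.class_probs)
        - node.left.n_samples / node.n_samples * gini(node.left.class_probs)
        - node.right.n_samples / node.n_samples * gini(node.right.class_probs)
    )


def feature_importance(forest: ForestModel) -> dict[str, float]:
    """Mean-decrease-impurity FIS per feature; unused features get 0."""
    totals = {m: 0.0 for m in forest.feature_ids}
    for root in forest.trees:
        stack = [root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            totals[node.feature] += (
                node.n_samples / forest.n_train_samples * delta_gini(node)
            )
            stack.append(node.left)
            stack.append(node.right)
    t = len(forest.trees)
    return {m: v / t for m, v in totals.items()}


def _convert_sklearn_tree(tree, feature_ids: Sequence[str]) -> TreeNode:
    """Extract an sklearn tree into the explicit TreeNode structure.

    Class counts at each node come from ``tree_.value`` scaled back to the
    bootstrap-weighted sample counts; probabilities are their normalization.
    """
    t = tree.tree_

    def build(i: int) -> TreeNode:
        counts = np.asarray(t.value[i], dtype=float).ravel()
        counts = counts * t.weighted_n_node_samples[i] / max(counts.sum(), 1e-300)
        probs = counts / counts.sum()
        if t.children_left[i] == -1:
            return TreeNode(n_samples=float(t.weighted_n_node_samples[i]),
                            class_probs=probs)
        return TreeNode(
            n_samples=float(t.weighted_n_node_samples[i]),
            class_probs=probs,
            feature=feature_ids[t.feature[i]],
            threshold=float(t.threshold[i]),
            left=build(t.children_left[i]),
            right=build(t.children_right[i]),
        )

    return build(0)


def _aligned_labels(rmes: RMESMatrix, labels: ContextLabels) -> tuple[np.ndarray, np.ndarray]:
    """Rows of the RMES matrix with a context label, and those labels.

    Unlabeled samples are allowed in the matrix and silently excluded here.
    """
    idx = [i for i, s in enumerate(rmes.sample_ids) if s in labels.assignments]
    if not idx:
        raise ValueError("no labeled sample is present in the RMES matrix")
    y = np.array([labels.assignments[rmes.sample_ids[i]] for i in idx])
    return np.array(idx), y


def train_ovr_forest(
    rmes: RMESMatrix,
    labels: ContextLabels,
    context: str,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> ForestModel:
    """Train the one-vs-rest Gini forest for one context.

    Standard random-forest regime: bootstrap resampling per tree (bootstrap
    size = number of labeled samples) and sqrt(K) feature subsampling per
    split. Deterministic for a fixed seed.
    """
    if context not in labels.contexts:
        raise ValueError(f"unknown context {context!r}")
    idx, y_ctx = _aligned_labels(rmes, labels)
    y = (y_ctx == context).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            f"context {context!r} needs both positive and negative samples"
        )
    X = rmes.scores[idx]
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
    )
    clf.fit(X, y)
    trees = [_convert_sklearn_tree(est, rmes.module_ids) for est in clf.estimators_]
    return ForestModel(
        trees=trees,
        n_train_samples=len(y),
        feature_ids=list(rmes.module_ids),
        context=context,
    )


def module_status(
    rmes: RMESMatrix, labels: ContextLabels, context: str, module_id: str
) -> str:
    """up_regulated iff the module's mean NES is higher in the positives."""
    idx, y_ctx = _aligned_labels(rmes, labels)
    mask = y_ctx == context
    if not mask.any() or mask.all():
        raise ValueError(
            f"context {context!r} needs both positive and negative samples"
        )
    col = rmes.column(module_id)[idx]
    return UP if col[mask].mean() > col[~mask].mean() else DOWN


def rank_modules(
    rmes: RMESMatrix,
    labels: ContextLabels,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    top_n: int | None = None,
) -> dict[str, pd.DataFrame]:
    """One ranked module table per context.

    Each table has columns (rank, module_id, fis, status), sorted by FIS
    descending with ties broken by module_id (FIS ties occur at 0), and is
    truncated to ``top_n`` rows when given.
    """
    tables: dict[str, pd.DataFrame] = {}
    for context in labels.contexts:
        forest = train_ovr_forest(rmes, labels, context, n_trees=n_trees, seed=seed)
        fis = feature_importance(forest)
        order = sorted(fis, key=lambda m: (-fis[m], m))
        if top_n is not None:
            order = order[:top_n]
        rows = [
            {
                "rank": r,
                "module_id": m,
                "fis": fis[m],
                "status": module_status(rmes, labels, context, m),
            }
            for r, m in enumerate(order, start=1)
        ]
        tables[context] = pd.DataFrame(
            rows, columns=["rank", "module_id", "fis", "status"]
        )
    return tables
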