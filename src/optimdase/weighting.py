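"""Gini-impurity feature weighting from fitted tree ensembles.

Each decision-tree node splitting on feature *i* contributes a score
derived from the Gini impurity of the node and its two children; the raw
importance of a feature is the sum of those scores over every tree in
the forest, and the weight vector is the importance vector normalized to
sum to 1.

Two child-combination conventions are available:

``weighted`` (default)
    The standard size-weighted impurity decrease
    ``S = G_parent − (n_L/n) G_left − (n_R/n) G_right``, which is
    non-negative and consistent with choosing the split that most
    reduces impurity.
``as_printed``
    The raw difference ``S = G_parent − G_left − G_right``, kept for
    auditability; it can go negative.

For regression forests the same node walk uses the variance (MSE)
impurity recorded at each node instead of the Gini impurity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NodeCounts",
    "ImportanceAccumulator",
    "WeightVector",
    "gini_node",
    "node_score",
    "accumulate_importance",
    "normalize_weights",
    "GiniFeatureWeighter",
]


@dataclass(frozen=True)
class NodeCounts:
    """Class-1 / class-0 instance counts at a single tree node."""

    n_positive: float
    n_negative: float

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> float:
        return self.n_positive + self.n_negative


@dataclass
class ImportanceAccumulator:
    """Raw per-feature importances summed over all trees of a forest."""

    importances: np.ndarray
    n_trees: int


@dataclass
class WeightVector:
    """Normalized per-feature weights; entries in [0, 1], summing to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1")

    def to_frame(self, feature_names) -> pd.DataFrame:
        """Two-column (feature, weight) table sorted by weight descending."""
        df = pd.DataFrame({"feature": list(feature_names), "weight": self.weights})
        return df.sort_values("weight", ascending=False, ignore_index=True)


def gini_node(counts: NodeCounts) -> float:
    """Binary Gini impurity ``1 − p₊² − p₋²``; 0 for a pure node, 0.5 at balance."""
    n = counts.n_total
    if n <= 0:
        raise ValueError("Gini impurity is undefined for an empty node")
    p_pos = counts.n_positive / n
    p_neg = counts.n_negative / n
    return 1.0 - p_pos**2 - p_neg**2


def node_score(
    parent: NodeCounts,
    left: NodeCounts,
    right: NodeCounts,
    convention: str = "weighted",
) -> float:
    """Split score of a node from parent and child impurities.

    The children must partition the parent's instances class by class.
    An empty child contributes 0 impurity under either convention.
    """
    if not (
        np.isclose(left.n_positive + right.n_positive, parent.n_positive)
        and np.isclose(left.n_negative + right.n_negative, parent.n_negative)
    ):
        raise ValueError("children do not partition the parent's instances")
    g_parent = gini_node(parent)
    g_left = gini_node(left) if left.n_total > 0 else 0.0
    g_right = gini_node(right) if right.n_total > 0 else 0.0
    if convention == "weighted":
        n = parent.n_total
        return g_parent - (left.n_total / n) * g_left - (right.n_total / n) * g_right
    if convention == "as_printed":
        return g_parent - g_left - g_right
    raise ValueError(f"unknown convention {convention!r}")


def _node_counts(tree, node: int) -> NodeCounts:
    """Recover per-class instance counts at a node of a fitted sklearn tree."""
    value = np.asarray(tree.value[node][0], dtype=float)
    total = tree.weighted_n_node_samples[node]
    frac = value / value.sum()
    return NodeCounts(n_positive=frac[1] * total, n_negative=frac[0] * total)


def _walk_classifier_tree(tree, importances: np.ndarray, convention: str) -> None:
    for node in range(tree.node_count):
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:  # leaf
            continue
        importances[tree.feature[node]] += node_score(
            _node_counts(tree, node),
            _node_counts(tree, left),
            _node_counts(tree, right),
            convention=convention,
        )


def _walk_regressor_tree(tree, importances: np.ndarray) -> None:
    # variance-reduction analogue: impurity is the node MSE
    for node in range(tree.node_count):
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:
            continue
        n = tree.weighted_n_node_samples[node]
        decrease = (
            tree.impurity[node]
            - tree.weighted_n_node_samples[left] / n * tree.impurity[left]
            - tree.weighted_n_node_samples[right] / n * tree.impurity[right]
        )
        importances[tree.feature[node]] += decrease


def accumulate_importance(forest, convention: str = "weighted") -> ImportanceAccumulator:
    """Sum node scores per feature over every tree of a fitted forest.

    Works on any sklearn-style tree ensemble exposing ``estimators_``;
    binary classifiers use the Gini node scores, regressors the variance
    reduction.  A feature never used in a split keeps importance 0.
    """
    check_is_fitted(forest, "estimators_")
    importances = np.zeros(forest.n_features_in_, dtype=float)
    is_classifier = hasattr(forest, "classes_")
    if is_classifier and len(forest.classes_) != 2:
        raise ValueError("Gini weighting is defined for binary classification only")
    for est in forest.estimators_:
        tree = est.tree_
        if is_classifier:
            _walk_classifier_tree(tree, importances, convention)
        else:
            _walk_regressor_tree(tree, importances)
    return ImportanceAccumulator(importances=importances, n_trees=len(forest.estimators_))


def normalize_weights(acc: ImportanceAccumulator) -> WeightVector:
    """``W_i = I_i / Σ_j I_j``; requires at least one informative split."""
    total = acc.importances.sum()
    if total <= 0:
        raise ValueError("all importances are zero; no informative splits recorded")
    return WeightVector(weights=acc.importances / total)


class GiniFeatureWeighter(BaseEstimator):
    """Fit a random forest and derive normalized per-feature weights.

    Parameters
    ----------
    n_estimators : int, default=100
        Trees in the auxiliary forest.
    convention : {"weighted", "as_printed"}, default="weighted"
        Child-impurity combination used in the node score.
    task : {"classification", "regression"}, default="classification"
    random_state : int or None

    Attributes
    ----------
    forest_ : the fitted auxiliary forest
    importances_ : raw summed node scores per feature
    weights_ : normalized weights, summing to 1
    """

    def __init__(
        self,
        n_estimators: int = 100,
        convention: str = "weighted",
        task: str = "classification",
        random_state: int | None = None,
        max_depth: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.convention = convention
        self.task = task
        self.random_state = random_state
        self.max_depth = max_depth

    def fit(self, X, y):
        if self.task == "classification":
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=self.random_state,
                n_jobs=1,
            )
        elif self.task == "regression":
            forest = RandomForestRegressor(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                random_state=self.random_state,
                n_jobs=1,
            )
        else:
            raise ValueError(f"unknown task {self.task!r}")
        forest.fit(np.asarray(X, dtype=float), y)
        acc = accumulate_importance(forest, convention=self.convention)
        self.forest_ = forest
        self.importances_ = acc.importances
        self.weights_ = normalize_weights(acc).weights
        return self
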