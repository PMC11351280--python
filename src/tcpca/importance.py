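"""Random-forest Gini feature importance and longitudinal profiles.

The node impurity is the Gini index ``1 - sum_c p_c^2``. A split on feature
x_j contributes the change of impurity before and after branching,
``GI_parent - GI_left - GI_right`` — accumulated literally, without child
sample weighting — summed over a feature's occurrences within a tree and
over all trees, then normalized to sum to one. The conventional
sample-weighted impurity decrease is available behind ``weighted=True``.
Representative features are those whose normalized score is strictly greater
than a threshold (default 0.02). The longitudinal profile refits a forest on
each visit slice and stacks the normalized rows.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .cohort import LongitudinalCohort

__all__ = [
    "GiniImportance",
    "LongitudinalImportance",
    "node_gini",
    "forest_gini_importance",
    "representative_features",
    "longitudinal_importance",
    "REPRESENTATIVE_THRESHOLD",
    "FOREST_DEFAULTS",
]

REPRESENTATIVE_THRESHOLD = 0.02
FOREST_DEFAULTS: Mapping = {"n_estimators": 500, "max_features": "sqrt"}


def node_gini(class_proportions: Sequence[float]) -> float:
    """Gini impurity ``1 - sum_c p_c^2`` of a class-proportion vector."""
    p = np.asarray(class_proportions, dtype=float)
    if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must be a simplex vector")
    return float(1.0 - np.sum(p**2))


@dataclasses.dataclass
class GiniImportance:
    """Per-feature accumulated impurity-decrease scores."""

    scores: np.ndarray
    normalized: bool
    n_trees: int
    class_count: int
    feature_names: list | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.normalized and abs(self.scores.sum() - 1.0) > 1e-12:
            raise ValueError("normalized scores must sum to 1")


def _node_ginis(tree) -> np.ndarray:
    counts = tree.value[:, 0, :]  # per-node class counts or fractions
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("tree lacks per-node class counts")
    p = counts / totals
    return 1.0 - np.sum(p**2, axis=1)


def forest_gini_importance(
    forest, n_features: int, normalize: bool = True, weighted: bool = False
) -> GiniImportance:
    """Accumulate per-split impurity changes over a fitted tree ensemble.

    ``weighted=False`` (default) subtracts child impurities directly;
    ``weighted=True`` weights children by their sample fractions (the
    standard mean-decrease-impurity variant).
    """
    estimators = getattr(forest, "estimators_", None)
    if estimators is None:
        raise ValueError("forest must be a fitted ensemble with estimators_")
    scores = np.zeros(n_features)
    n_classes = 0
    for est in estimators:
        tree = est.tree_
        gini = _node_ginis(tree)
        n_classes = max(n_classes, tree.value.shape[2])
        left, right, feat = tree.children_left, tree.children_right, tree.feature
        internal = left >= 0
        if weighted:
            w = tree.weighted_n_node_samples
            contrib = gini[internal] - (
                w[left[internal]] * gini[left[internal]]
                + w[right[internal]] * gini[right[internal]]
            ) / w[internal]
        else:
            contrib = (
                gini[internal] - gini[left[internal]] - gini[right[internal]]
            )
        np.add.at(scores, feat[internal], contrib)
    if normalize:
        total = scores.sum()
        if abs(total) < 1e-300:
            raise ValueError("total importance is zero; cannot normalize")
        scores = scores / total
    return GiniImportance(
        scores=scores,
        normalized=normalize,
        n_trees=len(estimators),
        class_count=n_classes,
    )


def representative_features(
    imp: GiniImportance, threshold: float = REPRESENTATIVE_THRESHOLD
) -> list[tuple[object, float]]:
    """Features with normalized importance strictly greater than ``threshold``,
    ordered by descending score. Returns (name-or-index, score) pairs."""
    if not imp.normalized:
        raise ValueError("representative_features requires normalized importance")
    names = (
        imp.feature_names
        if imp.feature_names is not None
        else list(range(imp.scores.size))
    )
    order = np.argsort(-imp.scores, kind="stable")
    return [
        (names[j], float(imp.scores[j])) for j in order if imp.scores[j] > threshold
    ]


@dataclasses.dataclass
class LongitudinalImportance:
    """Visit × feature matrix of normalized scores, one independent row per visit."""

    matrix: np.ndarray  # (p, k)
    visit_labels: list
    feature_names: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each visit row must sum to 1")


def _make_forest(forest_spec: Mapping | None, seed: int | None) -> RandomForestClassifier:
    params = {**FOREST_DEFAULTS, **dict(forest_spec or {})}
    return RandomForestClassifier(random_state=seed, **params)


def longitudinal_importance(
    cohort: LongitudinalCohort,
    labels: np.ndarray,
    forest_spec: Mapping | None = None,
    seed: int = 0,
    weighted: bool = False,
) -> LongitudinalImportance:
    """Fit a fresh seeded forest on each visit's N × k slice and stack the
    normalized importance rows."""
    if not cohort.fully_observed:
        raise ValueError("longitudinal importance requires an imputed cohort")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain at least two classes")
    rows = []
    for t in range(cohort.n_visits):
        forest = _make_forest(forest_spec, seed + t)
        forest.fit(cohort.values[:, t, :], labels)
        imp = forest_gini_importance(
            forest, cohort.n_features, normalize=True, weighted=weighted
        )
        rows.append(imp.scores)
    return LongitudinalImportance(
        matrix=np.vstack(rows),
        visit_labels=list(cohort.visit_labels),
        feature_names=list(cohort.feature_names),
    )
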