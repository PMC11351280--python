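"""Subtype discovery on the contrastive representation.

Agglomerative (Ward, Euclidean) clustering of the flattened per-subject
representation, with the cluster count chosen by maximizing the mean
silhouette over a K range, and a before/after comparison that re-runs the
progression classifiers inside each cluster with unchanged hyperparameters.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .baselines import FeatureTable
from .core import Representation
from .evaluation import METRICS, ProgressionLabelSet, evaluate

__all__ = ["SubtypeModel", "fit_subtypes", "per_cluster_evaluation"]


@dataclasses.dataclass
class SubtypeModel:
    """Cluster assignments at the silhouette-maximizing K."""

    n_clusters: int
    assignments: np.ndarray
    silhouette_by_k: dict[int, float]
    linkage: str = "ward"
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        best = min(
            (k for k, s in self.silhouette_by_k.items()
             if s == max(self.silhouette_by_k.values()))
        )
        if self.n_clusters != best:
            raise ValueError("n_clusters is not the silhouette argmax")
        counts = np.bincount(self.assignments, minlength=self.n_clusters)
        if (counts[: self.n_clusters] == 0).any():
            raise ValueError("every cluster must be nonempty")


def _flat(rep) -> np.ndarray:
    if isinstance(rep, Representation):
        return rep.flat
    if isinstance(rep, FeatureTable):
        return rep.values
    return np.asarray(rep, dtype=float)


def fit_subtypes(
    rep,
    k_range: Sequence[int] = range(2, 11),
    linkage: str = "ward",
    metric: str = "euclidean",
) -> SubtypeModel:
    """Cut a hierarchical clustering at each K and keep the silhouette argmax.

    Ties prefer the smaller K. ``rep`` may be a Representation, FeatureTable
    or plain array.
    """
    x = _flat(rep)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2:
        raise ValueError("k_range must contain integers >= 2")
    if x.shape[0] <= max(k_range):
        raise ValueError("need more points than the largest K")
    if np.allclose(x, x[0], atol=0):
        raise ValueError("all points identical; silhouette undefined")
    silhouette_by_k: dict[int, float] = {}
    assignments_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        model = AgglomerativeClustering(n_clusters=k, linkage=linkage, metric=metric)
        labels = model.fit_predict(x)
        assignments_by_k[k] = labels
        silhouette_by_k[k] = float(silhouette_score(x, labels, metric=metric))
    best = min(k for k in k_range if silhouette_by_k[k] == max(silhouette_by_k.values()))
    return SubtypeModel(
        n_clusters=best,
        assignments=assignments_by_k[best],
        silhouette_by_k=silhouette_by_k,
        linkage=linkage,
        metric=metric,
    )


def _merge_invalid_clusters(
    x: np.ndarray, assignments: np.ndarray, labels: np.ndarray, min_members: int
) -> np.ndarray:
    """Fold clusters lacking 2 classes or enough members into the nearest
    centroid's cluster."""
    assignments = assignments.copy()
    while True:
        ids = np.unique(assignments)
        if ids.size == 1:
            return assignments
        bad = None
        for c in ids:
            sel = assignments == c
            classes, counts = np.unique(labels[sel], return_counts=True)
            # also require every class inside the cluster to fill the CV folds
            if sel.sum() < min_members or classes.size < 2 or counts.min() < min_members:
                bad = c
                break
        if bad is None:
            return assignments
        centroids = {c: x[assignments == c].mean(axis=0) for c in ids}
        others = [c for c in ids if c != bad]
        dists = cdist(
            centroids[bad][None, :], np.vstack([centroids[c] for c in others])
        )[0]
        dest = others[int(np.argmin(dists))]
        warnings.warn(
            f"cluster {bad} has too few members/classes; merged into {dest}",
            stacklevel=3,
        )
        assignments[assignments == bad] = dest


def per_cluster_evaluation(
    rep,
    labels: ProgressionLabelSet,
    model: SubtypeModel,
    classifier_spec,
    n_folds: int = 3,
    n_runs: int = 10,
    seed: int = 0,
) -> dict:
    """Pooled vs. within-cluster cross-validated metrics, same hyperparameters.

    "before" runs CV on all subjects; "after" runs CV inside each cluster and
    aggregates metrics weighted by cluster size. With a single cluster the two
    are computed identically.
    """
    x = _flat(rep)
    y = labels.labels
    if x.shape[0] != y.shape[0] or x.shape[0] != model.assignments.shape[0]:
        raise ValueError("representation, labels and assignments disagree on N")

    def entry_means(table_x, table_y):
        tab = FeatureTable(
            table_x, list(range(table_x.shape[1])), "rep",
            list(range(table_x.shape[0])),
        )
        lab = ProgressionLabelSet(table_y, labels.horizon_years)
        ent = evaluate(tab, lab, classifier_spec, n_folds=n_folds, n_runs=n_runs, seed=seed)
        return {m: ent.mean(m) for m in METRICS}

    before = entry_means(x, y)

    assignments = _merge_invalid_clusters(x, model.assignments, y, min_members=n_folds)
    after = {m: 0.0 for m in METRICS}
    per_cluster = {}
    n = x.shape[0]
    for c in np.unique(assignments):
        sel = assignments == c
        means = entry_means(x[sel], y[sel])
        per_cluster[int(c)] = {"size": int(sel.sum()), **means}
        for m in METRICS:
            after[m] += sel.sum() / n * means[m]

    return {"before": before, "after": after, "per_cluster": per_cluster}
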