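"""Progression labels, cross-validated evaluation, and model comparison.

Labels compare ordinal diagnosis (CN < MCI < dementia) at a 1/3/5-year
horizon against the end of the observation window: lower future status is
"better" (+1), higher is "worse" (-1), equal is "unchanged" (0).

Evaluation runs repeated seeded stratified k-fold cross-validation and
reports accuracy, macro recall and macro F1 with their SDs over runs x
folds. Model pairs sharing fold seeds are compared with a one-sided paired
t-test; a difference is called significant iff p <= 0.01 and T > 2.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .baselines import FeatureTable, make_representation
from .cohort import CohortPair

__all__ = [
    "ProgressionLabelSet",
    "EvalEntry",
    "TTestRecord",
    "EvalReport",
    "make_progression_labels",
    "make_classifier",
    "evaluate",
    "paired_model_test",
    "comparison_grid",
]

SIGNIFICANCE_ALPHA = 0.01
T_THRESHOLD = 2.0
METRICS = ("accuracy", "recall", "f1")


@dataclasses.dataclass
class ProgressionLabelSet:
    """Per-subject 3-class progression outcome at one horizon."""

    labels: np.ndarray  # values in {-1, 0, +1}
    horizon_years: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (-1, 0, 1)).all():
            raise ValueError("labels must be in {-1, 0, +1}")

    @property
    def class_counts(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in (1, -1, 0)}


def make_progression_labels(
    status_now: np.ndarray,
    status_future: np.ndarray,
    horizon_years: int,
) -> tuple[ProgressionLabelSet, np.ndarray]:
    """Label each subject by the change in ordinal status at the horizon.

    Subjects with a missing (NaN) status at either endpoint are dropped;
    returns the label set and the boolean keep mask aligned to the input.
    """
    status_now = np.asarray(status_now, dtype=float)
    status_future = np.asarray(status_future, dtype=float)
    if status_now.shape != status_future.shape:
        raise ValueError("status arrays must have equal length")
    keep = np.isfinite(status_now) & np.isfinite(status_future)
    delta = status_future[keep] - status_now[keep]
    labels = np.where(delta < 0, 1, np.where(delta > 0, -1, 0))
    return (
        ProgressionLabelSet(
            labels=labels,
            horizon_years=horizon_years,
            n_dropped=int((~keep).sum()),
        ),
        keep,
    )


#: Default classifier settings (the published runs leave these unstated).
CLASSIFIER_DEFAULTS: Mapping[str, Mapping] = {
    "mlp": {"hidden_layer_sizes": (100,), "max_iter": 500},
    "rf": {"n_estimators": 500},
    "knn": {"n_neighbors": 5},
}


def make_classifier(spec, random_state: int | None = None):
    """Instantiate a classifier from a spec.

    ``spec`` is 'mlp' | 'rf' | 'knn', a (name, params) tuple, or a callable
    ``random_state -> estimator``.
    """
    if callable(spec):
        return spec(random_state)
    if isinstance(spec, str):
        name, params = spec, {}
    else:
        name, params = spec
    name = name.lower()
    merged = {**CLASSIFIER_DEFAULTS.get(name, {}), **dict(params)}
    if name == "mlp":
        return MLPClassifier(random_state=random_state, **merged)
    if name == "rf":
        return RandomForestClassifier(random_state=random_state, **merged)
    if name == "knn":
        return KNeighborsClassifier(**merged)
    raise ValueError(f"unknown classifier {name!r}")


@dataclasses.dataclass
class EvalEntry:
    """Fold-level metric scores for one (method, classifier, horizon) cell."""

    scores: dict[str, np.ndarray]  # metric -> (n_runs * n_folds,)
    n_folds: int
    n_runs: int

    def mean(self, metric: str) -> float:
        return float(self.scores[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.scores[metric].std(ddof=1))


def _fold_metrics(clf, x_tr, y_tr, x_te, y_te, average: str) -> dict[str, float]:
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)
    return {
        "accuracy": accuracy_score(y_te, pred),
        "recall": recall_score(y_te, pred, average=average, zero_division=0),
        "f1": f1_score(y_te, pred, average=average, zero_division=0),
    }


def evaluate(
    table: FeatureTable,
    labels: ProgressionLabelSet,
    classifier_spec,
    n_folds: int = 3,
    n_runs: int = 10,
    seed: int = 0,
    average: str = "macro",
) -> EvalEntry:
    """Repeated seeded stratified k-fold CV of one representation.

    Splits depend only on (seed, run index, labels), so two representations
    evaluated with the same seed share identical folds — the pairing the
    t-test comparison requires.
    """
    x = table.values
    y = labels.labels
    if x.shape[0] != y.shape[0]:
        raise ValueError("feature table and labels disagree on N")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"a class has only {counts.min()} member(s); reduce n_folds={n_folds}"
        )
    scores: dict[str, list[float]] = {m: [] for m in METRICS}
    for run in range(n_runs):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + run)
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            clf = make_classifier(classifier_spec, random_state=seed + 1000 * run + fold)
            fm = _fold_metrics(clf, x[tr], y[tr], x[te], y[te], average)
            for m in METRICS:
                scores[m].append(fm[m])
    return EvalEntry(
        scores={m: np.array(v) for m, v in scores.items()},
        n_folds=n_folds,
        n_runs=n_runs,
    )


@dataclasses.dataclass
class TTestRecord:
    """One-sided paired t-test of mean(a - b) > 0 with the decision rule."""

    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


def paired_model_test(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> TTestRecord:
    """Test whether model A's paired fold scores exceed model B's.

    Significant iff p <= 0.01 and T > 2. Zero-variance difference vectors are
    degenerate: all-zero differences are not significant; constant nonzero
    differences are significant iff positive.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-D with equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired scores")
    diff = a - b
    if np.allclose(diff.std(), 0.0):
        mean = diff.mean()
        if np.isclose(mean, 0.0):
            return TTestRecord(0.0, 1.0, False, degenerate=True)
        sign = 1.0 if mean > 0 else -1.0
        return TTestRecord(
            sign * np.inf, 0.0 if mean > 0 else 1.0, mean > 0, degenerate=True
        )
    res = stats.ttest_rel(a, b, alternative="greater")
    t, p = float(res.statistic), float(res.pvalue)
    return TTestRecord(t, p, p <= SIGNIFICANCE_ALPHA and t > T_THRESHOLD)


@dataclasses.dataclass
class EvalReport:
    """Benchmark grid: per-cell fold scores plus significance vs. a reference."""

    entries: dict[tuple, EvalEntry]  # (method, classifier, horizon) -> entry
    ttests: dict[tuple, TTestRecord]  # (method, classifier, horizon, metric)
    reference: str
    classifier_settings: Mapping = dataclasses.field(default_factory=dict)

    def to_frame(self, metric: str = "accuracy") -> pd.DataFrame:
        """Mean (and significance dagger vs. the reference) per cell."""
        rows = []
        for (method, clf, horizon), entry in self.entries.items():
            rec = self.ttests.get((method, clf, horizon, metric))
            rows.append(
                {
                    "horizon": horizon,
                    "classifier": clf,
                    "method": method,
                    "mean": entry.mean(metric),
                    "sd": entry.sd(metric),
                    "reference_significant": None if rec is None else rec.significant,
                }
            )
        return pd.DataFrame(rows)


def comparison_grid(
    pair: CohortPair,
    labels_by_horizon: Mapping[int, ProgressionLabelSet],
    methods: Sequence[str],
    classifiers: Sequence,
    seed: int = 0,
    n_folds: int = 3,
    n_runs: int = 10,
    method_params: Mapping[str, Mapping] | None = None,
    reference: str = "TcPCA",
) -> EvalReport:
    """Evaluate the full method x classifier x horizon cross product.

    All cells at one horizon share fold seeds, so the reference method's
    scores are paired with every competitor's; each comparison is marked
    significant per the p <= 0.01 and T > 2 rule.
    """
    method_params = dict(method_params or {})
    tables = {
        m: make_representation(pair, m, method_params.get(m)) for m in methods
    }
    entries: dict[tuple, EvalEntry] = {}
    ttests: dict[tuple, TTestRecord] = {}
    for horizon, labels in labels_by_horizon.items():
        for clf in classifiers:
            clf_name = clf if isinstance(clf, str) else getattr(clf, "__name__", str(clf))
            for method in methods:
                entries[(method, clf_name, horizon)] = evaluate(
                    tables[method], labels, clf,
                    n_folds=n_folds, n_runs=n_runs, seed=seed,
                )
            if reference in methods:
                ref = entries[(reference, clf_name, horizon)]
                for method in methods:
                    if method == reference:
                        continue
                    other = entries[(method, clf_name, horizon)]
                    for metric in METRICS:
                        ttests[(method, clf_name, horizon, metric)] = paired_model_test(
                            ref.scores[metric], other.scores[metric]
                        )
    return EvalReport(
        entries=entries,
        ttests=ttests,
        reference=reference,
        classifier_settings={
            c if isinstance(c, str) else str(c): CLASSIFIER_DEFAULTS.get(
                c if isinstance(c, str) else "", {}
            )
            for c in classifiers
        },
    )
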