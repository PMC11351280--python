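"""Fireworks-algorithm hyperparameter search.

A population of "fireworks" explodes each generation: better fireworks earn
more displacement sparks within smaller amplitudes (local refinement), worse
ones fewer sparks within larger amplitudes (exploration); a handful of
Gaussian-mutation sparks add diversity; out-of-bounds sparks are mapped back
into the box modularly; the next generation keeps the elite best plus
fireworks drawn with probability proportional to crowding distance. Used
here to maximize downstream cross-validated accuracy over the contrastive
trade-off parameters (alpha_feature, alpha_time) in log10 space.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import core
from .cohort import CohortPair
from .evaluation import ProgressionLabelSet, make_classifier

__all__ = ["FWAConfig", "FWAResult", "optimize", "tune_alphas", "DEFAULT_LOG_ALPHA_BOUNDS"]

#: Search box for (log10 alpha_feature, log10 alpha_time).
DEFAULT_LOG_ALPHA_BOUNDS = ((-2.0, 3.0), (-2.0, 3.0))


@dataclasses.dataclass
class FWAConfig:
    """Fireworks-algorithm settings (maximization over a box)."""

    bounds: Sequence[tuple[float, float]]
    n_fireworks: int = 5
    total_sparks: int = 50
    amplitude_max: float = 1.0
    spark_min: int = 2
    spark_max: int = 40
    n_gaussian: int = 5
    max_evaluations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        if self.n_fireworks < 2:
            raise ValueError("n_fireworks must be >= 2")
        if not (1 <= self.spark_min <= self.spark_max <= self.total_sparks):
            raise ValueError("need 1 <= spark_min <= spark_max <= total_sparks")
        if self.amplitude_max <= 0:
            raise ValueError("amplitude_max must be positive")
        for lo, hi in self.bounds:
            if lo > hi:
                raise ValueError("each bound must satisfy low <= high")
        if self.max_evaluations < self.n_fireworks:
            raise ValueError("budget must cover the initial population")


@dataclasses.dataclass
class FWAResult:
    best_point: np.ndarray
    best_value: float
    history: list[float]
    evaluations_used: int


def _map_into_box(x: np.ndarray, low: np.ndarray, high: np.ndarray) -> np.ndarray:
    span = high - low
    out = x.copy()
    oob = (x < low) | (x > high)
    with np.errstate(invalid="ignore"):
        wrapped = low + np.abs(x - low) % np.where(span > 0, span, 1.0)
    out[oob] = wrapped[oob]
    out[:, span == 0] = low[span == 0]
    return out


def optimize(objective, config: FWAConfig) -> FWAResult:
    """Maximize ``objective`` over the configured box; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    low = np.array([b[0] for b in config.bounds])
    high = np.array([b[1] for b in config.bounds])
    d = low.size

    def evaluate(points: np.ndarray) -> np.ndarray:
        vals = np.empty(points.shape[0])
        for i, pt in enumerate(points):
            v = float(objective(pt))
            if not np.isfinite(v):
                raise ValueError(f"objective returned non-finite value at {pt}")
            vals[i] = v
        return vals

    x = rng.uniform(low, high, size=(config.n_fireworks, d))
    f = evaluate(x)
    used = config.n_fireworks
    best_idx = int(np.argmax(f))
    best_point, best_value = x[best_idx].copy(), float(f[best_idx])
    history = [best_value]
    eps = 1e-12

    while used < config.max_evaluations:
        fmax, fmin = f.max(), f.min()
        # fitness-proportional spark counts, inverse-fitness amplitudes
        rel = (f - fmin + eps) / (np.sum(f - fmin) + config.n_fireworks * eps)
        counts = np.clip(
            np.round(config.total_sparks * rel).astype(int),
            config.spark_min,
            config.spark_max,
        )
        amp_rel = (fmax - f + eps) / (np.sum(fmax - f) + config.n_fireworks * eps)
        amps = config.amplitude_max * amp_rel
        # minimum-amplitude safeguard: the raw rule assigns the best firework a
        # vanishing radius, stalling refinement; floor decays geometrically so
        # late generations still search finely around the incumbent
        progress = used / config.max_evaluations
        amps = np.maximum(amps, config.amplitude_max * 10.0 ** (-3.0 * progress))

        sparks = []
        for i in range(config.n_fireworks):
            for _ in range(counts[i]):
                z = rng.integers(1, d + 1)
                dims = rng.choice(d, size=z, replace=False)
                pt = x[i].copy()
                pt[dims] += amps[i] * rng.uniform(-1.0, 1.0, size=z)
                sparks.append(pt)
        for _ in range(config.n_gaussian):
            i = rng.integers(config.n_fireworks)
            z = rng.integers(1, d + 1)
            dims = rng.choice(d, size=z, replace=False)
            pt = x[i].copy()
            pt[dims] *= rng.normal(1.0, 1.0)
            sparks.append(pt)

        sparks = _map_into_box(np.asarray(sparks), low, high)
        remaining = config.max_evaluations - used
        sparks = sparks[:remaining]
        fs = evaluate(sparks)
        used += sparks.shape[0]

        pool = np.vstack([x, sparks])
        fp = np.concatenate([f, fs])
        top = int(np.argmax(fp))
        if fp[top] > best_value:
            best_value, best_point = float(fp[top]), pool[top].copy()
        history.append(best_value)

        # elite best + roulette on crowding distance
        others = np.delete(np.arange(pool.shape[0]), top)
        diffs = pool[others][:, None, :] - pool[None, :, :]
        crowd = np.sqrt((diffs**2).sum(axis=2)).sum(axis=1)
        if crowd.sum() <= 0:
            probs = np.full(others.size, 1.0 / others.size)
        else:
            probs = crowd / crowd.sum()
        n_pick = min(config.n_fireworks - 1, others.size)
        picked = rng.choice(others, size=n_pick, replace=False, p=probs)
        sel = np.concatenate([[top], picked])
        x, f = pool[sel], fp[sel]

    return FWAResult(
        best_point=best_point,
        best_value=best_value,
        history=history,
        evaluations_used=used,
    )


def cv_accuracy_objective(
    pair: CohortPair,
    labels: ProgressionLabelSet,
    classifier_spec,
    n_folds: int = 3,
    seed: int = 0,
    metric: str = "accuracy",
    m_feature: int | None = None,
    m_time: int | None = None,
):
    """Objective mapping (log10 alpha_feature, log10 alpha_time) to mean
    stratified CV accuracy (or macro F1) of the contrastive representation.

    Ranks are held fixed across candidate alphas (defaults min(10, k) and
    min(4, p)) so every candidate is scored on a representation of the same
    dimension — energy-based selection is unavailable at large alpha, where
    the contrast matrix is negative definite.
    """
    from sklearn.metrics import accuracy_score, f1_score

    y = labels.labels
    if np.unique(y).size < 2:
        raise ValueError("tuning requires at least two label classes")
    if m_feature is None:
        m_feature = min(10, pair.target.n_features)
    if m_time is None:
        m_time = min(4, pair.target.n_visits)

    def objective(log_alphas: np.ndarray) -> float:
        alpha_f, alpha_t = 10.0 ** np.asarray(log_alphas, dtype=float)
        basis = core.fit_tcpca(
            pair, alpha_f, alpha_t, m_feature=m_feature, m_time=m_time, mode="full"
        )
        rep = core.transform(basis, pair.target).flat
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = []
        for fold, (tr, te) in enumerate(skf.split(rep, y)):
            clf = make_classifier(classifier_spec, random_state=seed + fold)
            clf.fit(rep[tr], y[tr])
            pred = clf.predict(rep[te])
            if metric == "accuracy":
                scores.append(accuracy_score(y[te], pred))
            else:
                scores.append(f1_score(y[te], pred, average="macro", zero_division=0))
        return float(np.mean(scores))

    return objective


def tune_alphas(
    pair: CohortPair,
    labels: ProgressionLabelSet,
    classifier_spec="knn",
    config: FWAConfig | None = None,
    n_folds: int = 3,
    metric: str = "accuracy",
) -> tuple[float, float, FWAResult]:
    """Fireworks search for (alpha_feature, alpha_time) in log10 space.

    Returns the maximizing alphas on the natural scale plus the full search
    result (whose ``best_point`` is in log10 coordinates).
    """
    if config is None:
        config = FWAConfig(bounds=DEFAULT_LOG_ALPHA_BOUNDS, max_evaluations=60)
    objective = cv_accuracy_objective(
        pair, labels, classifier_spec, n_folds=n_folds, seed=config.seed, metric=metric
    )
    result = optimize(objective, config)
    alpha_f, alpha_t = 10.0 ** result.best_point
    return float(alpha_f), float(alpha_t), result
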