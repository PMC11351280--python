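"""Comparator representations for the progression-prediction benchmark.

OR flattens the raw subject matrices; SOR summarizes each feature's time
series with seven statistics; 2DPCA projects on the target cohort's
feature-axis eigenvectors without background subtraction; five kernel PCA
variants operate on the flattened view. Contrastive representations (full
and the two single-axis ablations) are reached through the same registry.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis, skew

from . import core
from .cohort import CohortPair, LongitudinalCohort

__all__ = [
    "FeatureTable",
    "represent_or",
    "represent_sor",
    "represent_2dpca",
    "represent_kernel_pca",
    "make_representation",
    "METHOD_TAGS",
    "SOR_STATISTICS",
]

SOR_STATISTICS = ("mean", "std", "max", "min", "var", "skew", "kurtosis")

#: Benchmark column order; the contrastive ablations are TcPCA0 (feature-only)
#: and TcPCA1 (time-only).
METHOD_TAGS = (
    "OR", "SOR", "2DPCA", "PCA1", "PCA2", "PCA3", "PCA4", "PCA5",
    "TcPCA0", "TcPCA1", "TcPCA",
)

_KERNEL_OF_TAG = {
    "PCA1": "rbf",
    "PCA2": "rational_quadratic",
    "PCA3": "linear",
    "PCA4": "polynomial",
    "PCA5": "sigmoid",
}


@dataclasses.dataclass
class FeatureTable:
    """One row of derived features per subject, in cohort order."""

    values: np.ndarray  # (N, d)
    columns: list
    method: str
    subject_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature table must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table entries must be finite")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column count mismatch")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("row count mismatch")


def represent_or(cohort: LongitudinalCohort) -> FeatureTable:
    """Raw visit-major flattening of each subject matrix (d = p·k)."""
    if not cohort.fully_observed:
        raise ValueError("OR requires an imputed cohort")
    flat = cohort.values.reshape(cohort.n_subjects, -1)
    cols = [
        f"{v}:{f}" for v in cohort.visit_labels for f in cohort.feature_names
    ]
    return FeatureTable(flat, cols, "OR", list(cohort.subject_ids))


def represent_sor(cohort: LongitudinalCohort) -> FeatureTable:
    """Seven per-feature time-series statistics (d = 7·k), statistic-major.

    Population variance; Fisher skewness and excess kurtosis, defined as 0
    for zero-variance series.
    """
    if not cohort.fully_observed:
        raise ValueError("SOR requires an imputed cohort")
    if cohort.n_visits < 2:
        raise ValueError("SOR needs at least 2 visits")
    x = cohort.values  # (N, p, k)
    sd = x.std(axis=1)
    degenerate = sd < 1e-12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sk = skew(x, axis=1, bias=True)
        ku = kurtosis(x, axis=1, fisher=True, bias=True)
    sk = np.where(degenerate, 0.0, np.nan_to_num(sk))
    ku = np.where(degenerate, 0.0, np.nan_to_num(ku))
    stats = {
        "mean": x.mean(axis=1),
        "std": sd,
        "max": x.max(axis=1),
        "min": x.min(axis=1),
        "var": x.var(axis=1),
        "skew": sk,
        "kurtosis": ku,
    }
    blocks = [stats[name] for name in SOR_STATISTICS]
    cols = [f"{name}:{f}" for name in SOR_STATISTICS for f in cohort.feature_names]
    return FeatureTable(
        np.concatenate(blocks, axis=1), cols, "SOR", list(cohort.subject_ids)
    )


def represent_2dpca(pair: CohortPair, m: int) -> FeatureTable:
    """Feature-axis PCA of the target cohort only; subjects mapped to S·M.

    Definitionally the alpha = 0, feature-only contrastive fit, but assembled
    directly from the target covariance here.
    """
    k = pair.target.n_features
    if not 1 <= m <= k:
        raise ValueError(f"m={m} out of range for k={k}")
    cov = core._cohort_axis_covariance(pair.target, "feature")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(-eigvals, kind="stable")[:m]
    basis = core._fix_signs(eigvecs[:, order])
    flat = np.einsum("itk,km->itm", pair.target.values, basis).reshape(
        pair.target.n_subjects, -1
    )
    cols = [f"{v}:pc{j}" for v in pair.target.visit_labels for j in range(m)]
    return FeatureTable(flat, cols, "2DPCA", list(pair.target.subject_ids))


def _kernel_matrix(x: np.ndarray, kernel: str, params: Mapping) -> np.ndarray:
    d = x.shape[1]
    gamma = params.get("gamma", 1.0 / d)
    if kernel == "linear":
        return x @ x.T
    if kernel == "polynomial":
        degree = params.get("degree", 3)
        coef0 = params.get("coef0", 1.0)
        return (gamma * (x @ x.T) + coef0) ** degree
    if kernel == "sigmoid":
        coef0 = params.get("coef0", 1.0)
        return np.tanh(gamma * (x @ x.T) + coef0)
    sq = np.sum(x * x, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    if kernel == "rbf":
        return np.exp(-gamma * d2)
    if kernel == "rational_quadratic":
        alpha = params.get("alpha", 1.0)
        if "length_scale" in params:
            ell = params["length_scale"]
        else:
            pair_d = pdist(x)
            ell = np.median(pair_d[pair_d > 0]) if np.any(pair_d > 0) else 1.0
        return (1.0 + d2 / (2.0 * alpha * ell**2)) ** (-alpha)
    raise ValueError(f"unknown kernel {kernel!r}")


def represent_kernel_pca(
    cohort: LongitudinalCohort,
    kernel: str,
    m: int,
    kernel_params: Mapping | None = None,
) -> FeatureTable:
    """Kernel PCA component scores on the flattened (OR) view.

    The Gram matrix is double-centered; scores are eigenvector columns scaled
    by sqrt(eigenvalue). Components with nonpositive eigenvalues (possible for
    the indefinite sigmoid kernel) are dropped with a warning.
    """
    or_table = represent_or(cohort)
    x = or_table.values
    n = x.shape[0]
    if not 1 <= m < n:
        raise ValueError(f"m={m} must satisfy 1 <= m < N={n}")
    kmat = _kernel_matrix(x, kernel, dict(kernel_params or {}))
    ones = np.full((n, n), 1.0 / n)
    kc = kmat - ones @ kmat - kmat @ ones + ones @ kmat @ ones
    kc = (kc + kc.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(kc)
    order = np.argsort(-eigvals, kind="stable")[:m]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > 1e-10
    if not keep.all():
        warnings.warn(
            f"kernel {kernel!r}: dropped {int((~keep).sum())} component(s) with "
            "nonpositive eigenvalues",
            stacklevel=2,
        )
        eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    scores = core._fix_signs(eigvecs) * np.sqrt(eigvals)
    cols = [f"{kernel}:pc{j}" for j in range(scores.shape[1])]
    return FeatureTable(scores, cols, f"kpca_{kernel}", list(cohort.subject_ids))


def make_representation(
    pair: CohortPair,
    method: str,
    params: Mapping | None = None,
) -> FeatureTable:
    """Build the target-cohort feature table for one benchmark method tag.

    ``params`` supplies method settings: contrastive methods take
    ``alpha_feature``/``alpha_time`` (default 1.0) plus optional ranks or
    ``energy``; 2DPCA and kernel methods take ``m`` (defaults: energy-selected
    rank for 2DPCA, 10 for kernel PCA) and kernel hyperparameters.
    """
    params = dict(params or {})
    if method == "OR":
        return represent_or(pair.target)
    if method == "SOR":
        return represent_sor(pair.target)
    if method == "2DPCA":
        m = params.get("m")
        if m is None:
            cov_f = core.contrastive_covariance(pair, "feature", 0.0)
            cov_t = core.contrastive_covariance(pair, "time", 0.0)
            m, _ = core.select_ranks(cov_f, cov_t, params.get("energy", 0.9))
        return represent_2dpca(pair, m)
    if method in _KERNEL_OF_TAG:
        m = params.get("m", min(10, pair.target.n_subjects - 1))
        return represent_kernel_pca(
            pair.target, _KERNEL_OF_TAG[method], m, params.get("kernel_params")
        )
    if method in ("TcPCA", "TcPCA0", "TcPCA1"):
        mode = {"TcPCA": "full", "TcPCA0": "feature_only", "TcPCA1": "time_only"}[method]
        basis = core.fit_tcpca(
            pair,
            alpha_feature=params.get("alpha_feature", 1.0),
            alpha_time=params.get("alpha_time", 1.0),
            m_feature=params.get("m_feature"),
            m_time=params.get("m_time"),
            mode=mode,
            energy=params.get("energy", 0.9),
        )
        rep = core.transform(basis, pair.target)
        cols = [
            f"t{a}:f{b}" for a in range(basis.m_time) for b in range(basis.m_feature)
        ]
        return FeatureTable(rep.flat, cols, method, list(pair.target.subject_ids))
    raise ValueError(f"unknown method tag {method!r}; expected one of {METHOD_TAGS}")
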