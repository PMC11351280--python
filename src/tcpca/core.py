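"""Tensorized contrastive PCA.

Contrastive PCA finds directions of variance enriched in a target cohort
relative to a background cohort by eigendecomposing ``C_target - alpha *
C_background``. Here both the feature axis (k × k covariances of the p × k
subject matrices) and the time axis (p × p) are decomposed, and each subject
is projected bilinearly::

    S_change = M_time.T @ S @ M_feature

``alpha`` trades retention of target variance against suppression of
background ("natural aging") variance; one alpha per axis. ``alpha = 0``
on both axes reduces to ordinary two-sided PCA of the target cohort.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .cohort import CohortPair, LongitudinalCohort

__all__ = [
    "ContrastiveCovariance",
    "ContrastiveBasis",
    "Representation",
    "contrastive_covariance",
    "top_contrastive_directions",
    "select_ranks",
    "fit_tcpca",
    "transform",
]

Axis = Literal["feature", "time"]
Mode = Literal["full", "feature_only", "time_only"]


@dataclasses.dataclass
class ContrastiveCovariance:
    """Target and background covariances on one axis, plus their contrast."""

    axis: Axis
    c_target: np.ndarray
    c_background: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        for name in ("c_target", "c_background"):
            c = getattr(self, name)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError(f"{name} not symmetric")
        if self.c_target.shape != self.c_background.shape:
            raise ValueError("target/background covariance shapes differ")

    @property
    def combined(self) -> np.ndarray:
        return self.c_target - self.alpha * self.c_background


def _cohort_axis_covariance(cohort: LongitudinalCohort, axis: Axis) -> np.ndarray:
    """(1/N) sum_i centered S_i^T S_i (feature axis) or S_i S_i^T (time axis).

    Each cohort is centered by its own mean tensor.
    """
    if not cohort.fully_observed:
        raise ValueError("covariance requires an imputed cohort (mask all True)")
    n = cohort.n_subjects
    if n < 2:
        raise ValueError("covariance requires at least 2 subjects")
    centered = cohort.values - cohort.values.mean(axis=0)
    if axis == "feature":
        c = np.einsum("itj,itl->jl", centered, centered) / n
    elif axis == "time":
        c = np.einsum("itj,isj->ts", centered, centered) / n
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return (c + c.T) / 2.0


def contrastive_covariance(
    pair: CohortPair, axis: Axis, alpha: float
) -> ContrastiveCovariance:
    """Assemble target/background covariances on one axis and their contrast."""
    return ContrastiveCovariance(
        axis=axis,
        c_target=_cohort_axis_covariance(pair.target, axis),
        c_background=_cohort_axis_covariance(pair.background, axis),
        alpha=float(alpha),
    )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-magnitude entry is positive."""
    vectors = vectors.copy()
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def top_contrastive_directions(
    cov: ContrastiveCovariance, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-m eigenvectors of the (symmetric, possibly indefinite) contrast.

    Ranked by algebraically largest eigenvalue — the argmax of the contrastive
    variance objective; the contrast need not be positive semidefinite. Exact
    eigenvalue ties keep the solver's original index order; each column's sign
    is fixed so its largest-magnitude entry is positive.
    """
    combined = cov.combined
    d = combined.shape[0]
    if not 1 <= m <= d:
        raise ValueError(f"m={m} out of range for dimension {d}")
    eigvals, eigvecs = np.linalg.eigh((combined + combined.T) / 2.0)
    order = np.argsort(-eigvals, kind="stable")[:m]
    return _fix_signs(eigvecs[:, order]), eigvals[order]


def _rank_by_energy(cov: ContrastiveCovariance, energy: float) -> int:
    if not 0 < energy <= 1:
        raise ValueError("energy must lie in (0, 1]")
    eigvals = np.sort(np.linalg.eigvalsh(cov.combined))[::-1]
    pos = eigvals[eigvals > 0]
    if pos.size == 0:
        raise ValueError(
            f"no positive eigenvalue on the {cov.axis} axis: cohorts are "
            "indistinguishable at this alpha"
        )
    frac = np.cumsum(pos) / pos.sum()
    return int(np.searchsorted(frac, energy - 1e-15) + 1)


def select_ranks(
    cov_feature: ContrastiveCovariance,
    cov_time: ContrastiveCovariance,
    energy: float = 0.9,
) -> tuple[int, int]:
    """Smallest rank per axis capturing >= ``energy`` of positive-eigenvalue mass."""
    return _rank_by_energy(cov_feature, energy), _rank_by_energy(cov_time, energy)


@dataclasses.dataclass
class ContrastiveBasis:
    """Fitted projection bases for both axes.

    ``feature_basis`` is k × m_feature, ``time_basis`` is p × m_time, both
    column-orthonormal. Eigenvalue arrays are None for an axis represented by
    the identity (ablation modes). Cohort mean tensors are carried for
    reference; projection itself applies no re-centering.
    """

    feature_basis: np.ndarray
    time_basis: np.ndarray
    eigvals_feature: np.ndarray | None
    eigvals_time: np.ndarray | None
    alpha_feature: float
    alpha_time: float
    mode: Mode
    target_mean: np.ndarray | None = None
    background_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("feature_basis", "time_basis"):
            b = getattr(self, name)
            gram = b.T @ b
            if not np.allclose(gram, np.eye(b.shape[1]), atol=1e-8):
                raise ValueError(f"{name} columns not orthonormal")
        for ev in (self.eigvals_feature, self.eigvals_time):
            if ev is not None and ev.size > 1 and np.any(np.diff(ev) > 1e-10):
                raise ValueError("eigenvalues must be non-increasing")

    @property
    def m_feature(self) -> int:
        return self.feature_basis.shape[1]

    @property
    def m_time(self) -> int:
        return self.time_basis.shape[1]


def fit_tcpca(
    pair: CohortPair,
    alpha_feature: float,
    alpha_time: float,
    m_feature: int | None = None,
    m_time: int | None = None,
    mode: Mode = "full",
    energy: float = 0.9,
    rank_fallback: int | None = None,
) -> ContrastiveBasis:
    """Fit contrastive bases on the feature and/or time axes.

    ``mode='feature_only'`` replaces the time basis with the p × p identity;
    ``'time_only'`` replaces the feature basis with the k × k identity. Ranks
    default to the smallest capturing ``energy`` of positive eigenvalue mass.
    At large alpha the contrast can be negative definite, leaving no positive
    mass; ``rank_fallback`` then supplies the rank for that axis (directions
    are still the algebraically largest), instead of raising.
    """
    p = pair.target.n_visits
    k = pair.target.n_features
    if mode not in ("full", "feature_only", "time_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if m_feature is not None and m_feature > k:
        raise ValueError(f"m_feature={m_feature} exceeds k={k}")
    if m_time is not None and m_time > p:
        raise ValueError(f"m_time={m_time} exceeds p={p}")

    def auto_rank(cov: ContrastiveCovariance, dim: int) -> int:
        try:
            return _rank_by_energy(cov, energy)
        except ValueError:
            if rank_fallback is None:
                raise
            return min(rank_fallback, dim)

    if mode == "time_only":
        feature_basis, eig_f = np.eye(k), None
    else:
        cov_f = contrastive_covariance(pair, "feature", alpha_feature)
        mf = m_feature if m_feature is not None else auto_rank(cov_f, k)
        feature_basis, eig_f = top_contrastive_directions(cov_f, mf)
    if mode == "feature_only":
        time_basis, eig_t = np.eye(p), None
    else:
        cov_t = contrastive_covariance(pair, "time", alpha_time)
        mt = m_time if m_time is not None else auto_rank(cov_t, p)
        time_basis, eig_t = top_contrastive_directions(cov_t, mt)

    return ContrastiveBasis(
        feature_basis=feature_basis,
        time_basis=time_basis,
        eigvals_feature=eig_f,
        eigvals_time=eig_t,
        alpha_feature=float(alpha_feature),
        alpha_time=float(alpha_time),
        mode=mode,
        target_mean=pair.target.values.mean(axis=0),
        background_mean=pair.background.values.mean(axis=0),
    )


@dataclasses.dataclass
class Representation:
    """Per-subject projected matrices plus a flattened view for classifiers."""

    matrices: np.ndarray  # (N, m_time, m_feature)
    subject_ids: list
    basis: ContrastiveBasis | None = None

    @property
    def flat(self) -> np.ndarray:
        """Row-major (time-major) unfolding, N × (m_time · m_feature)."""
        return self.matrices.reshape(self.matrices.shape[0], -1)


def transform(basis: ContrastiveBasis, cohort: LongitudinalCohort) -> Representation:
    """Project every subject: ``S_change = M_time.T @ S @ M_feature``.

    The cohort must be on the same scaling as the pair used at fit time.
    """
    if not cohort.fully_observed:
        raise ValueError("transform requires an imputed cohort")
    p, k = cohort.n_visits, cohort.n_features
    if basis.time_basis.shape[0] != p or basis.feature_basis.shape[0] != k:
        raise ValueError(
            f"basis shapes (p={basis.time_basis.shape[0]}, k={basis.feature_basis.shape[0]}) "
            f"do not match cohort (p={p}, k={k})"
        )
    mats = np.einsum("tm,itk,kf->imf", basis.time_basis, cohort.values, basis.feature_basis)
    return Representation(matrices=mats, subject_ids=list(cohort.subject_ids), basis=basis)
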