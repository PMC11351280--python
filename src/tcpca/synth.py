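"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the contrastive decomposition assumes:
both cohorts share a dominant low-rank "natural aging" variance structure
(orthonormal feature directions paired with smooth monotone time profiles),
while the target cohort carries additional disease structure on feature
directions orthogonal to aging, with late-onset time ramps, planted subtype
centroids in disease-score space, imbalanced 3-class progression labels
linked to the disease scores, and optional uniform missingness.

Every draw comes from one seeded generator, so a spec + seed fully
determines the cohorts, labels, masks and planted axes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import CohortPair, LongitudinalCohort

__all__ = ["SyntheticSpec", "SynthTruth", "generate", "published_scale_spec"]


@dataclasses.dataclass
class SyntheticSpec:
    """Generator settings; defaults are the desk-scale study conditions.

    Variance shares are fractions of each cohort's total cell variance:
    ``var_aging`` for the shared aging block (both cohorts), ``var_disease``
    for the target-only disease block, the remainder white noise. Within a
    block, axes get geometrically decreasing shares so each block has a
    well-defined leading planted direction. ``subtype_separation`` is the
    minimum centroid distance in within-subtype-SD units; subtype spread is
    folded into the disease variance share. ``label_proportions`` are the
    target frequencies of the (better, worse, unchanged) = (+1, -1, 0)
    progression classes.
    """

    n_target: int = 400
    n_background: int = 200
    p: int = 8
    k: int = 60
    n_aging_axes: int = 3
    n_disease_axes: int = 1
    var_aging: float = 0.6
    var_disease: float = 0.15
    noise_sd: float = 1.0
    n_subtypes: int = 4
    subtype_separation: float = 10.0
    label_proportions: tuple[float, float, float] = (67.0, 198.0, 1644.0)
    label_slope: float = 2.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.var_aging < 1 and 0 < self.var_disease < 1):
            raise ValueError("variance shares must lie in (0, 1)")
        if self.var_aging + self.var_disease >= 1:
            raise ValueError("var_aging + var_disease must be < 1")
        if self.n_aging_axes + self.n_disease_axes > self.k:
            raise ValueError("more planted axes than features")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")
        if min(self.label_proportions) <= 0:
            raise ValueError("label proportions must be positive")


@dataclasses.dataclass
class SynthTruth:
    """Planted ground truth accompanying a generated pair."""

    labels: np.ndarray  # (n_target,) in {-1, 0, +1}
    subtypes: np.ndarray  # (n_target,) cluster index
    aging_feature_axes: np.ndarray  # (k, n_aging)
    aging_time_profiles: np.ndarray  # (p, n_aging)
    disease_feature_axes: np.ndarray  # (k, n_disease)
    disease_time_profiles: np.ndarray  # (p, n_disease)
    aging_scales: np.ndarray
    disease_scales: np.ndarray
    disease_scores: np.ndarray  # (n_target, n_disease) normalized scores


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _smooth_monotone_profiles(p: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm, smoothly increasing time profiles (aging-like drift)."""
    t = np.linspace(0.0, 1.0, p)
    profiles = np.empty((p, n))
    for j in range(n):
        steep = rng.uniform(2.0, 6.0)
        mid = rng.uniform(0.3, 0.7)
        profiles[:, j] = _unit(1.0 / (1.0 + np.exp(-steep * (t - mid))) + 0.2)
    return profiles


def _late_onset_profiles(p: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-norm ramps that stay near zero early and rise in late visits."""
    t = np.linspace(0.0, 1.0, p)
    profiles = np.empty((p, n))
    for j in range(n):
        onset = rng.uniform(0.35, 0.6)
        ramp = np.clip((t - onset) / max(1.0 - onset, 1e-9), 0.0, None) ** 1.5
        profiles[:, j] = _unit(ramp + 0.02)
    return profiles


def _block_shares(n: int, ratio: float = 0.5) -> np.ndarray:
    """Geometric within-block variance shares summing to 1 (leading axis dominant)."""
    w = ratio ** np.arange(n)
    return w / w.sum()


def _subtype_centroids(n_subtypes: int, dim: int, separation: float) -> np.ndarray:
    """Centroids with minimum pairwise distance = separation (within-SD units)."""
    if n_subtypes == 1:
        return np.zeros((1, dim))
    if dim >= 2 and n_subtypes == 4:
        base = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float) / 2.0
        cent = np.zeros((4, dim))
        cent[:, :2] = base * separation  # adjacent corners are `separation` apart
        return cent
    # general case: spread along the leading disease axis
    cent = np.zeros((n_subtypes, dim))
    cent[:, 0] = (np.arange(n_subtypes) - (n_subtypes - 1) / 2.0) * separation
    return cent


def _assemble(
    scores: np.ndarray, scales: np.ndarray, time_profiles: np.ndarray, feat_axes: np.ndarray
) -> np.ndarray:
    """sum_a scale_a * score_ia * (u_a outer v_a) -> (N, p, k) tensor."""
    return np.einsum("ia,a,ta,ka->itk", scores, scales, time_profiles, feat_axes)


def generate(spec: SyntheticSpec) -> tuple[CohortPair, SynthTruth]:
    """Draw a target/background pair plus the planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    p, k = spec.p, spec.k
    na, nd = spec.n_aging_axes, spec.n_disease_axes

    # orthonormal feature directions; first na aging, remaining nd disease
    basis, _ = np.linalg.qr(rng.standard_normal((k, na + nd)))
    aging_axes, disease_axes = basis[:, :na], basis[:, na:]
    aging_profiles = _smooth_monotone_profiles(p, na, rng)
    disease_profiles = _late_onset_profiles(p, nd, rng)

    # per-cohort total cell variance implied by the noise share
    noise_var = spec.noise_sd**2 * p * k
    total_target = noise_var / (1.0 - spec.var_aging - spec.var_disease)
    total_background = noise_var / (1.0 - spec.var_aging)
    aging_scales_t = np.sqrt(spec.var_aging * total_target * _block_shares(na))
    aging_scales_b = np.sqrt(spec.var_aging * total_background * _block_shares(na))
    disease_scales = np.sqrt(spec.var_disease * total_target * _block_shares(nd))

    # disease scores: subtype centroid + unit noise, rescaled to unit variance
    # so the subtype spread stays inside the disease variance budget
    subtypes = rng.integers(spec.n_subtypes, size=spec.n_target)
    centroids = _subtype_centroids(spec.n_subtypes, nd, spec.subtype_separation)
    raw_scores = centroids[subtypes] + rng.standard_normal((spec.n_target, nd))
    scale_back = np.sqrt(1.0 + centroids.var(axis=0))
    disease_scores = raw_scores / scale_back

    aging_scores_t = rng.standard_normal((spec.n_target, na))
    aging_scores_b = rng.standard_normal((spec.n_background, na))

    target_values = (
        _assemble(aging_scores_t, aging_scales_t, aging_profiles, aging_axes)
        + _assemble(disease_scores, disease_scales, disease_profiles, disease_axes)
        + spec.noise_sd * rng.standard_normal((spec.n_target, p, k))
    )
    background_values = _assemble(
        aging_scores_b, aging_scales_b, aging_profiles, aging_axes
    ) + spec.noise_sd * rng.standard_normal((spec.n_background, p, k))

    # ordinal progression labels from a noisy logistic latent on the leading
    # disease score; cutpoints calibrated to the requested class proportions
    props = np.asarray(spec.label_proportions, dtype=float)
    props = props / props.sum()  # (better, worse, unchanged)
    latent = spec.label_slope * disease_scores[:, 0] + rng.logistic(
        size=spec.n_target
    )
    lo = np.quantile(latent, props[0])
    hi = np.quantile(latent, 1.0 - props[1])
    labels = np.where(latent <= lo, 1, np.where(latent > hi, -1, 0))

    months = np.arange(p, dtype=float) * 6.0
    visit_labels = [f"m{int(m):02d}" for m in months]
    feature_names = [f"f{j:03d}" for j in range(k)]

    def to_cohort(values: np.ndarray, prefix: str) -> LongitudinalCohort:
        n = values.shape[0]
        mask = np.ones(values.shape, dtype=bool)
        if spec.missing_rate > 0:
            mask = rng.random(values.shape) >= spec.missing_rate
            values = np.where(mask, values, np.nan)
        return LongitudinalCohort(
            values=values,
            mask=mask,
            subject_ids=[f"{prefix}{i:04d}" for i in range(n)],
            visit_labels=visit_labels,
            visit_months=months,
            feature_names=feature_names,
        )

    pair = CohortPair(
        target=to_cohort(target_values, "tar"),
        background=to_cohort(background_values, "bck"),
    )
    truth = SynthTruth(
        labels=labels,
        subtypes=subtypes,
        aging_feature_axes=aging_axes,
        aging_time_profiles=aging_profiles,
        disease_feature_axes=disease_axes,
        disease_time_profiles=disease_profiles,
        aging_scales=aging_scales_t,
        disease_scales=disease_scales,
        disease_scores=disease_scores,
    )
    return pair, truth


def published_scale_spec(k: int = 60, seed: int = 0) -> SyntheticSpec:
    """Spec at the published cohort scale: 1909/884 subjects, 8 visits,
    1-year label proportions 67:198:1644 (better:worse:unchanged).

    ``k`` defaults to 60 for desk-scale runs; set 872 for full scale.
    """
    return SyntheticSpec(
        n_target=1909,
        n_background=884,
        p=8,
        k=k,
        label_proportions=(67.0, 198.0, 1644.0),
        seed=seed,
    )
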