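# Methods

## Model

A longitudinal cohort is a tensor of `N` subjects × `p` visits × `k`
features; subject `i` contributes the matrix `S_i` (`p × k`). Two cohorts are
analyzed jointly: a *target* cohort (disease) and a *background* cohort
(never-diseased), assumed to share the variance structure of normal aging
while only the target carries disease-specific structure.

Per axis, cohort covariances are assembled after centering each cohort by its
own mean tensor `S̄ = (1/N) Σ_i S_i`:

- feature axis: `C^feature = (1/N) Σ_i (S_i − S̄)ᵀ(S_i − S̄)` (`k × k`),
- time axis: `C^time = (1/N) Σ_i (S_i − S̄)(S_i − S̄)ᵀ` (`p × p`).

The notation for the centering term is ambiguous between a per-subject and a
cohort mean; only the cohort-mean reading yields nonzero covariances, so that
is what is implemented. The contrastive matrix on each axis is
`C_target − α · C_background`, symmetrized as `(C + Cᵀ)/2` before
eigendecomposition for numerical safety. Directions are ranked by
**algebraic** eigenvalue: the contrast is generally indefinite — and at large
α negative definite, since the background's isotropic noise floor is also
scaled by α — yet the argmax of the contrastive variance objective is still
the algebraically largest eigenvector. Eigenvector signs are fixed so each
column's largest-magnitude entry is positive, and exact eigenvalue ties keep
the solver's index order, making outputs reproducible across platforms.

Each subject is projected bilinearly, `S_i^change = M_timeᵀ S_i M_feature`,
with no re-centering at projection time (centering information lives in the
standardization record). With full orthonormal bases the projection is an
isometry (`‖S_i^change‖_F = ‖S_i‖_F`); the flattened row-major view feeds
classifiers and clustering.

## Parameters

- **α_feature, α_time ≥ 0** — trade-off between retaining target variance
  and suppressing background variance, one per axis. `α = 0` is two-sided
  PCA of the target. On the planted benchmark the aging structure flips to
  negative eigenvalues once α exceeds the ratio of target to background
  aging scale (≈1.6 under the defaults), so any moderate α beyond that
  isolates disease structure; the tuner searches `[10⁻², 10³]` per axis in
  log₁₀ space.
- **m_feature ≤ k, m_time ≤ p** — basis ranks. Default: smallest rank
  capturing 90% of the *positive* eigenvalue mass per axis. When the
  contrast is negative definite (large α) no positive mass exists; callers
  either pass explicit ranks or set `rank_fallback` (the tuning objective
  holds ranks fixed — `min(10, k)` and `min(4, p)` — so all candidate alphas
  are scored on a representation of the same dimension).
- **Imputation** — each missing cell takes the mean of that cell over the
  `n_neighbors = 5` subjects nearest in Euclidean distance on jointly
  observed cells (per-pair mean squared difference, so unequal overlap does
  not bias distances); last-observation-carried-forward is available as an
  alternative mode. Observed cells are never altered.
- **Standardization** — per (visit, feature) cell z-scoring with mean/SD
  pooled over both cohorts, so the contrastive subtraction compares like
  scales; zero-SD cells map to 0 and are flagged. The stored record applies
  the identical transform to held-out subjects.
- **Visit grid** — default 8 semiannual visits (months 0–42), configurable;
  subjects observed at fewer than half the grid visits are dropped.
- **Classifiers** — MLP (one hidden layer of 100), random forest (500
  trees), KNN (k = 5); all seeded, all recorded in reports.
- **Gini importance** — per split, the impurity change
  `GI_parent − GI_left − GI_right` is accumulated *without* child sample
  weighting, summed over a feature's occurrences and over trees, then
  normalized to sum to 1. This literal rule is the default; the conventional
  sample-weighted mean decrease in impurity sits behind `weighted=True`.
  Note the unweighted rule is not sign-bounded: a split can contribute
  negatively, so normalized scores may exceed 1 or dip below 0 on individual
  features while still summing to 1. Representative features are those with
  normalized score **strictly** greater than 0.02.
- **Subtyping** — Ward linkage on Euclidean distances of the flattened
  representation (configurable to complete/average), cut at each K in 2–10;
  the mean-silhouette argmax wins, ties preferring smaller K. Within-cluster
  evaluation reuses the pooled classifier hyperparameters and aggregates
  metrics weighted by cluster size; clusters too small (or too
  single-classed) to host the CV folds are merged into the nearest
  centroid's cluster with a warning.

## Fireworks optimizer

The tuner maximizes mean seeded stratified 3-fold CV accuracy (macro F1
optional) over `(log₁₀ α_feature, log₁₀ α_time)`. Each generation, fireworks
emit displacement sparks — counts proportional to relative fitness (clamped
to `[spark_min, spark_max]`), amplitudes inversely proportional to fitness —
plus a few Gaussian-mutation sparks; out-of-bounds sparks are mapped back by
modular reflection into the box; the next generation keeps the elite best
and fills the rest by roulette on crowding distance. Two deliberate choices:
a geometrically decaying minimum amplitude (from `amplitude_max` down to
`10⁻³ · amplitude_max` over the budget) keeps the incumbent refining — the
raw inverse-fitness rule assigns it a vanishing radius and stalls — and
selection is simplified to elite-plus-distance-roulette for reproducibility.
The evaluation budget is counted and never exceeded; per-generation best
values are non-decreasing by elitism; a fixed seed reproduces the entire
trajectory bit for bit.

## Synthetic cohorts

The generator emulates the statistical situation the method assumes, not any
real dataset's marginals. Both cohorts share `n_aging_axes = 3` rank-one
aging components: random orthonormal feature directions paired with smooth,
monotone sigmoid time profiles ("functions drift with age"), with
geometrically decreasing shares inside the block so the leading aging axis
is well defined. The target cohort adds a single disease component — a
feature direction orthogonal to the aging directions paired with a
late-onset ramp profile — carrying the whole disease variance share; the
planted disease axis is therefore unambiguous, and the four subtypes are
centroid shifts of the disease score (minimum centroid distance 10 within-SD
units, rescaled so the subtype spread stays inside the disease variance
budget). Remaining variance is white noise. Default shares: aging 0.60,
disease 0.15, per cohort's own total, at N = 400 target / 200 background,
p = 8, k = 60 (desk scale); a published-scale preset provides N = 1909/884
with 1-year class proportions 67 : 198 : 1644 (better : worse : unchanged).
Progression labels come from a logistic-noise latent on the disease score
with cutpoints calibrated to the requested class proportions.

What passing tests show — and do not. Recovery results on these cohorts
demonstrate that the estimator finds low-rank structure enriched in the
target when such structure exists and is linear, rank-one per component, and
orthogonal to the background structure. Real clinical data offer none of
those guarantees: modalities have heterogeneous units and missingness
mechanisms, aging and disease axes need not be orthogonal, and effects are
not rank-one. Passing here validates the machinery, not clinical claims.

## Numerical choices and degenerate inputs

Covariances require N ≥ 2 and fully imputed cohorts. Rank selection raises
when the contrast has no positive eigenvalue unless a fallback rank is
given. The paired t-test treats zero-variance difference vectors explicitly:
all-zero differences are not significant; constant nonzero differences are
significant iff positive, flagged degenerate. Silhouette selection refuses
all-identical inputs. Constant time series get skewness/kurtosis 0 in the
SOR summary (population variance throughout; the choice is documented
because it changes values, though not rankings). Kernel PCA drops components
with nonpositive eigenvalues of the double-centered Gram matrix (the sigmoid
kernel is indefinite) with a warning. Deterministic tie-breaks: stable sorts
everywhere, eigenvector sign by largest-magnitude entry, silhouette ties to
smaller K.

## Problem sizes

The test suite runs the full stack at desk scale (k = 60) and one smoke pass
at the published dimensionality (p = 8, k = 872, ~600 subjects), which
completes in a few minutes on one CPU; the acceptance script uses desk scale
with a 40-evaluation tuning budget and finishes in well under a minute.
These sizes were chosen to keep iteration fast while exercising every code
path at full dimensionality at least once.

## Known limitations

- The two ablation representations are tagged TcPCA0 (feature-only) and
  TcPCA1 (time-only) by this package's own convention.
- The per-axis α tuning objective is a single shared CV accuracy; axes are
  not tuned against axis-specific criteria.
- Nearest-subject imputation is O(N²) in subjects via three Gram products;
  fine to a few thousand subjects, not engineered beyond that.
- No sparse-tensor or streaming support; cohorts are dense in memory.
- Cluster-count selection by silhouette inherits silhouette's bias toward
  compact, balanced, spherical clusters.
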