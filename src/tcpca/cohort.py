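"""Longitudinal cohort data model.

A cohort is a subject × visit × feature tensor with an observation mask.
Each subject contributes one ``p × k`` matrix slice (``p`` visits, ``k``
features); visits sit on a fixed grid of month offsets. Loading, visit-grid
alignment, nearest-subject imputation and per-cell standardization live here —
everything upstream of the contrastive decomposition.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_VISIT_MONTHS",
    "LongitudinalCohort",
    "CohortPair",
    "CellScaler",
    "load_long_table",
    "align_time_grid",
    "impute_missing",
    "standardize",
]

#: Default semiannual visit grid: 8 visits spanning 42 months.
DEFAULT_VISIT_MONTHS: Mapping[str, float] = {
    f"m{m:02d}": float(m) for m in range(0, 48, 6)
}


@dataclasses.dataclass
class LongitudinalCohort:
    """Subject × visit × feature tensor with observation mask and metadata.

    Parameters
    ----------
    values : ndarray of shape (N, p, k)
        Measurements; entries where ``mask`` is False are ignored (may be NaN).
    mask : boolean ndarray of shape (N, p, k)
        True where the cell was observed.
    subject_ids : sequence of N identifiers, sorted.
    visit_labels : p visit labels, ordered by month offset.
    visit_months : ndarray of p strictly increasing month offsets.
    feature_names : k unique feature names.
    status : optional (N, p) ordinal diagnosis codes (0=CN, 1=MCI, 2=dementia),
        NaN where unknown.
    """

    values: np.ndarray
    mask: np.ndarray
    subject_ids: list
    visit_labels: list
    visit_months: np.ndarray
    feature_names: list
    status: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.visit_months = np.asarray(self.visit_months, dtype=float)
        self.subject_ids = list(self.subject_ids)
        self.visit_labels = list(self.visit_labels)
        self.feature_names = list(self.feature_names)
        n, p, k = self.values.shape
        if n < 1 or p < 1 or k < 1:
            raise ValueError("cohort must have N >= 1, p >= 1, k >= 1")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")
        if len(self.visit_labels) != p or self.visit_months.shape != (p,):
            raise ValueError("visit grid length mismatch")
        if len(self.feature_names) != k:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != k:
            raise ValueError("feature_names must be unique")
        if p > 1 and not np.all(np.diff(self.visit_months) > 0):
            raise ValueError("visit_months must be strictly increasing")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed values must be finite")
        if self.status is not None:
            self.status = np.asarray(self.status, dtype=float)
            if self.status.shape != (n, p):
                raise ValueError("status must have shape (N, p)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_visits(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    @property
    def fully_observed(self) -> bool:
        return bool(self.mask.all())

    def copy(self) -> "LongitudinalCohort":
        return LongitudinalCohort(
            values=self.values.copy(),
            mask=self.mask.copy(),
            subject_ids=list(self.subject_ids),
            visit_labels=list(self.visit_labels),
            visit_months=self.visit_months.copy(),
            feature_names=list(self.feature_names),
            status=None if self.status is None else self.status.copy(),
        )


@dataclasses.dataclass
class CohortPair:
    """A target (disease) cohort and a background (never-diseased) cohort.

    Both cohorts must share the same visit grid and feature names so that the
    contrastive subtraction compares like quantities.
    """

    target: LongitudinalCohort
    background: LongitudinalCohort

    def __post_init__(self) -> None:
        if self.target.feature_names != self.background.feature_names:
            raise ValueError("target and background feature names differ")
        if self.target.visit_labels != self.background.visit_labels or not np.allclose(
            self.target.visit_months, self.background.visit_months
        ):
            raise ValueError("target and background visit grids differ")


def load_long_table(
    path,
    id_column: str,
    visit_column: str,
    status_column: str | None = None,
    visit_months: Mapping[str, float] | None = None,
    feature_columns: Sequence[str] | None = None,
) -> LongitudinalCohort:
    """Load a long-format CSV (one row per subject-visit) into a cohort tensor.

    ``visit_months`` maps visit labels to month offsets; if None, labels must
    parse as numeric months. Subjects are sorted by ID and visits by month, so
    row order in the file never affects the output. Absent subject-visit rows
    and empty cells become masked-out entries.
    """
    frame = pd.read_csv(path)
    for col in (id_column, visit_column):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if status_column is not None and status_column not in frame.columns:
        raise ValueError(f"status column {status_column!r} not found")

    dup = frame.duplicated(subset=[id_column, visit_column], keep=False)
    if dup.any():
        first = frame.loc[dup, [id_column, visit_column]].iloc[0]
        raise ValueError(
            f"duplicate (subject, visit) pair: ({first[id_column]!r}, {first[visit_column]!r})"
        )

    labels_in_file = [str(v) for v in frame[visit_column].unique()]
    if visit_months is None:
        try:
            visit_months = {lab: float(lab) for lab in labels_in_file}
        except ValueError as exc:
            raise ValueError(
                "visit labels are not numeric; provide a visit_months mapping"
            ) from exc
    unknown = [lab for lab in labels_in_file if lab not in visit_months]
    if unknown:
        raise ValueError(f"unknown visit label(s): {unknown}")

    order = sorted(visit_months, key=lambda lab: visit_months[lab])
    months = np.array([visit_months[lab] for lab in order], dtype=float)
    visit_index = {lab: t for t, lab in enumerate(order)}

    reserved = {id_column, visit_column}
    if status_column is not None:
        reserved.add(status_column)
    if feature_columns is None:
        feature_columns = [c for c in frame.columns if c not in reserved]
    feature_columns = list(feature_columns)
    if not feature_columns:
        raise ValueError("no feature columns found")

    subjects = sorted(frame[id_column].astype(str).unique())
    sub_index = {s: i for i, s in enumerate(subjects)}
    n, p, k = len(subjects), len(order), len(feature_columns)

    values = np.full((n, p, k), np.nan)
    mask = np.zeros((n, p, k), dtype=bool)
    status = np.full((n, p), np.nan) if status_column is not None else None

    # errors='raise' distinguishes genuinely non-numeric cells from blanks
    feats = frame[feature_columns].apply(pd.to_numeric, errors="raise")
    rows_i = frame[id_column].astype(str).map(sub_index).to_numpy()
    rows_t = frame[visit_column].astype(str).map(visit_index).to_numpy()
    vals = feats.to_numpy(dtype=float)
    values[rows_i, rows_t, :] = vals
    mask[rows_i, rows_t, :] = np.isfinite(vals)
    if status is not None:
        status[rows_i, rows_t] = pd.to_numeric(
            frame[status_column], errors="raise"
        ).to_numpy(dtype=float)

    return LongitudinalCohort(
        values=values,
        mask=mask,
        subject_ids=subjects,
        visit_labels=order,
        visit_months=months,
        feature_names=feature_columns,
        status=status,
    )


def align_time_grid(
    cohort: LongitudinalCohort,
    grid: Sequence[str],
    months: Mapping[str, float] | None = None,
    min_fraction: float = 0.5,
) -> LongitudinalCohort:
    """Restrict/reorder a cohort onto a fixed visit grid.

    Visits outside ``grid`` are dropped; grid visits absent from the cohort
    become fully masked columns. Subjects observed (any feature) at fewer than
    ``min_fraction`` of the grid visits are removed and reported via a warning.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty visit grid")
    month_of = dict(zip(cohort.visit_labels, cohort.visit_months))
    if months is not None:
        month_of.update(months)
    missing = [g for g in grid if g not in month_of]
    if missing:
        raise ValueError(f"no month offset known for grid visit(s): {missing}")

    order = sorted(grid, key=lambda lab: month_of[lab])
    n, _, k = cohort.values.shape
    p = len(order)
    values = np.full((n, p, k), np.nan)
    mask = np.zeros((n, p, k), dtype=bool)
    status = None if cohort.status is None else np.full((n, p), np.nan)
    src = {lab: t for t, lab in enumerate(cohort.visit_labels)}
    for t, lab in enumerate(order):
        if lab in src:
            values[:, t, :] = cohort.values[:, src[lab], :]
            mask[:, t, :] = cohort.mask[:, src[lab], :]
            if status is not None:
                status[:, t] = cohort.status[:, src[lab]]

    observed_visits = mask.any(axis=2).sum(axis=1)
    keep = observed_visits >= min_fraction * p
    if not keep.any():
        raise ValueError("all subjects dropped by the visit-retention rule")
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [cohort.subject_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"align_time_grid dropped {n_dropped} subject(s) observed at fewer "
            f"than {min_fraction:.0%} of grid visits: {dropped[:10]}",
            stacklevel=2,
        )

    return LongitudinalCohort(
        values=values[keep],
        mask=mask[keep],
        subject_ids=[s for s, kp in zip(cohort.subject_ids, keep) if kp],
        visit_labels=order,
        visit_months=np.array([month_of[lab] for lab in order], dtype=float),
        feature_names=list(cohort.feature_names),
        status=None if status is None else status[keep],
    )


def _pairwise_masked_distances(flat: np.ndarray, mflat: np.ndarray) -> np.ndarray:
    """Mean squared difference over jointly observed cells, for all pairs.

    Expands sum_j m_i m_j (x_i - x_j)^2 into three Gram products so the whole
    N x N matrix comes from matmuls. Pairs with no joint cells get +inf.
    """
    x = np.where(mflat, flat, 0.0)
    x2 = x * x
    m = mflat.astype(float)
    cross = x @ x.T
    s1 = x2 @ m.T
    counts = m @ m.T
    d2 = s1 + s1.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, d2 / np.maximum(counts, 1.0), np.inf)
    np.fill_diagonal(out, np.inf)
    return np.maximum(out, 0.0)


def impute_missing(
    cohort: LongitudinalCohort, n_neighbors: int = 5, mode: str = "knn"
) -> LongitudinalCohort:
    """Fill masked cells; the output mask is all-True.

    ``knn`` (default): each missing cell gets the mean of that cell over the
    ``n_neighbors`` subjects nearest in Euclidean distance on jointly observed
    cells — the most literal reading of "supplemented using similar diagnostic
    results". ``locf`` carries the last observation forward along the visit
    axis (then backward for leading gaps), falling back to the per-cell mean.
    Observed cells are never altered.
    """
    if cohort.fully_observed:
        return cohort.copy()
    if mode not in ("knn", "locf"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    n, p, k = cohort.values.shape
    cell_observed = cohort.mask.any(axis=0)
    if not cell_observed.all():
        t, f = np.argwhere(~cell_observed)[0]
        raise ValueError(
            f"cell (visit={cohort.visit_labels[t]}, feature={cohort.feature_names[f]}) "
            "is observed in no subject"
        )
    values = cohort.values.copy()
    mask = cohort.mask

    if mode == "locf":
        for i in range(n):
            for f in range(k):
                col = values[i, :, f]
                obs = mask[i, :, f]
                if not obs.any():
                    col[:] = np.nan
                    continue
                idx = np.where(obs, np.arange(p), -1)
                np.maximum.accumulate(idx, out=idx)
                filled = np.where(idx >= 0, col[np.maximum(idx, 0)], np.nan)
                # leading gap: backfill from first observation
                first = np.argmax(obs)
                filled[:first] = col[first]
                values[i, :, f] = filled
        still = ~np.isfinite(values)
        if still.any():
            cell_mean = np.nanmean(np.where(mask, cohort.values, np.nan), axis=0)
            values = np.where(still, np.broadcast_to(cell_mean, values.shape), values)
    else:
        if n_neighbors < 1:
            raise ValueError("n_neighbors must be positive")
        flat = cohort.values.reshape(n, -1)
        mflat = mask.reshape(n, -1)
        dist = _pairwise_masked_distances(flat, mflat)
        filled = values.reshape(n, -1)
        for cell in np.flatnonzero(~mflat.all(axis=0)):
            observers = np.flatnonzero(mflat[:, cell])
            needers = np.flatnonzero(~mflat[:, cell])
            d = dist[np.ix_(needers, observers)]
            # stable nearest-neighbor order: distance, then subject index
            order = np.argsort(d, axis=1, kind="stable")[:, :n_neighbors]
            neigh_vals = flat[observers[order], cell]
            filled[needers, cell] = neigh_vals.mean(axis=1)
        values = filled.reshape(n, p, k)

    out = cohort.copy()
    out.values = values
    out.mask = np.ones_like(mask)
    return out


@dataclasses.dataclass
class CellScaler:
    """Per-(visit, feature) standardization record.

    Means/SDs are pooled over target+background subjects; ``degenerate`` marks
    zero-SD cells whose standardized value is defined as 0.
    """

    mean: np.ndarray  # (p, k)
    sd: np.ndarray  # (p, k)
    degenerate: np.ndarray  # (p, k) bool

    def transform(self, cohort: LongitudinalCohort) -> LongitudinalCohort:
        out = cohort.copy()
        sd = np.where(self.degenerate, 1.0, self.sd)
        out.values = (cohort.values - self.mean) / sd
        out.values[:, self.degenerate] = 0.0
        out.values = np.where(cohort.mask, out.values, np.nan)
        return out


def standardize(pair: CohortPair) -> tuple[CohortPair, CellScaler]:
    """Z-score every (visit, feature) cell using pooled target+background stats.

    Requires imputed cohorts (all cells observed). Returns the standardized
    pair plus the scaling record needed to transform held-out subjects
    identically.
    """
    if not (pair.target.fully_observed and pair.background.fully_observed):
        raise ValueError("standardize requires imputed cohorts (mask all True)")
    pooled = np.concatenate([pair.target.values, pair.background.values], axis=0)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    degenerate = sd < 1e-12
    scaler = CellScaler(mean=mean, sd=sd, degenerate=degenerate)
    return CohortPair(scaler.transform(pair.target), scaler.transform(pair.background)), scaler
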