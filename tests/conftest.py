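import numpy as np
import pytest

import tcpca


def make_cohort(values, mask=None, status=None, prefix="s"):
    """Wrap a raw (N, p, k) array in a LongitudinalCohort with stock metadata."""
    values = np.asarray(values, dtype=float)
    n, p, k = values.shape
    return tcpca.LongitudinalCohort(
        values=values,
        mask=np.ones_like(values, dtype=bool) if mask is None else mask,
        subject_ids=[f"{prefix}{i:03d}" for i in range(n)],
        visit_labels=[f"m{6 * t:02d}" for t in range(p)],
        visit_months=np.arange(p, dtype=float) * 6.0,
        feature_names=[f"f{j:03d}" for j in range(k)],
        status=status,
    )


@pytest.fixture(scope="session")
def planted():
    """Desk-scale planted pair with known aging/disease axes (fixed seed)."""
    return tcpca.generate(tcpca.SyntheticSpec(seed=1))


@pytest.fixture()
def tiny_pair(rng_factory):
    """Small integer-valued pair for brute-force covariance oracles."""
    rng = rng_factory(42)
    target = make_cohort(rng.integers(-3, 4, size=(3, 2, 2)).astype(float), prefix="t")
    background = make_cohort(
        rng.integers(-3, 4, size=(4, 2, 2)).astype(float), prefix="b"
    )
    return tcpca.CohortPair(target=target, background=background)


@pytest.fixture(scope="session")
def rng_factory():
    return np.random.default_rng
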