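"""Contrastive covariances, eigen-ranking, bilinear projection, rank selection."""

import numpy as np
import pytest

import tcpca
from conftest import make_cohort
from tcpca.core import _rank_by_energy


def brute_force_feature_covariance(values):
    """Literal double-loop of the feature-axis covariance definition."""
    n, p, k = values.shape
    mean = values.mean(axis=0)
    acc = np.zeros((k, k))
    for i in range(n):
        d = values[i] - mean
        acc += d.T @ d
    return acc / n


def brute_force_time_covariance(values):
    n, p, k = values.shape
    mean = values.mean(axis=0)
    acc = np.zeros((p, p))
    for i in range(n):
        d = values[i] - mean
        acc += d @ d.T
    return acc / n


class TestContrastiveCovariance:
    def test_matches_brute_force_summation(self, tiny_pair):
        cov_f = tcpca.contrastive_covariance(tiny_pair, "feature", 0.7)
        cov_t = tcpca.contrastive_covariance(tiny_pair, "time", 0.7)
        np.testing.assert_allclose(
            cov_f.c_target,
            brute_force_feature_covariance(tiny_pair.target.values),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            cov_f.c_background,
            brute_force_feature_covariance(tiny_pair.background.values),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            cov_t.c_target,
            brute_force_time_covariance(tiny_pair.target.values),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            cov_f.combined, cov_f.c_target - 0.7 * cov_f.c_background, atol=1e-12
        )

    def test_alpha_zero_reduces_to_target_covariance(self, tiny_pair):
        cov = tcpca.contrastive_covariance(tiny_pair, "feature", 0.0)
        np.testing.assert_array_equal(cov.combined, cov.c_target)

    def test_identical_cohorts_cancel_at_alpha_one(self, tiny_pair):
        pair = tcpca.CohortPair(tiny_pair.target, tiny_pair.target.copy())
        cov = tcpca.contrastive_covariance(pair, "feature", 1.0)
        assert np.abs(cov.combined).max() < 1e-12

    def test_single_subject_cohort_rejected(self):
        single = make_cohort(np.zeros((1, 2, 2)))
        pair = tcpca.CohortPair(single, single.copy())
        with pytest.raises(ValueError, match="at least 2"):
            tcpca.contrastive_covariance(pair, "feature", 1.0)


class TestTopContrastiveDirections:
    def _cov_with_combined(self, combined):
        d = combined.shape[0]
        return tcpca.ContrastiveCovariance(
            axis="feature", c_target=combined, c_background=np.zeros((d, d)), alpha=0.0
        )

    def test_identity_matrix_degenerate_spectrum(self):
        basis, eigvals = tcpca.top_contrastive_directions(
            self._cov_with_combined(np.eye(3)), 2
        )
        np.testing.assert_allclose(eigvals, [1.0, 1.0])
        np.testing.assert_allclose(basis.T @ basis, np.eye(2), atol=1e-10)

    def test_diagonal_matrix_orders_by_algebraic_value(self):
        basis, eigvals = tcpca.top_contrastive_directions(
            self._cov_with_combined(np.diag([3.0, 1.0, -2.0])), 2
        )
        np.testing.assert_allclose(eigvals, [3.0, 1.0])
        np.testing.assert_allclose(np.abs(basis), np.eye(3)[:, :2], atol=1e-12)
        assert basis[0, 0] > 0 and basis[1, 1] > 0  # sign convention

    def test_random_symmetric_matches_dense_solver(self, rng_factory):
        rng = rng_factory(3)
        a = rng.normal(size=(6, 6))
        combined = (a + a.T) / 2
        basis, eigvals = tcpca.top_contrastive_directions(
            self._cov_with_combined(combined), 6
        )
        # diagonalizes with descending diagonal
        diag = basis.T @ combined @ basis
        np.testing.assert_allclose(diag, np.diag(eigvals), atol=1e-9)
        assert np.all(np.diff(eigvals) <= 1e-12)
        ref = np.sort(np.linalg.eigvalsh(combined))[::-1]
        np.testing.assert_allclose(eigvals, ref, atol=1e-9)

    def test_m_beyond_dimension_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            tcpca.top_contrastive_directions(self._cov_with_combined(np.eye(3)), 4)


class TestFitTcpca:
    def test_alpha_zero_equals_two_sided_pca_of_target(self, planted):
        pair, _ = planted
        basis = tcpca.fit_tcpca(pair, 0.0, 0.0, m_feature=3, m_time=2)
        cov_f = brute_force_feature_covariance(pair.target.values)
        cov_t = brute_force_time_covariance(pair.target.values)
        for cov, fitted, m in (
            (cov_f, basis.feature_basis, 3),
            (cov_t, basis.time_basis, 2),
        ):
            eigvals, eigvecs = np.linalg.eigh(cov)
            ref = eigvecs[:, np.argsort(-eigvals)[:m]]
            # principal angles between fitted and reference subspaces
            sv = np.linalg.svd(ref.T @ fitted, compute_uv=False)
            angles = np.arccos(np.clip(sv, -1, 1))
            assert angles.max() < 1e-6

    def test_single_visit_reduces_to_matrix_cpca(self, rng_factory):
        rng = rng_factory(7)
        target = make_cohort(rng.normal(size=(30, 1, 5)), prefix="t")
        background = make_cohort(rng.normal(size=(25, 1, 5)), prefix="b")
        pair = tcpca.CohortPair(target, background)
        basis = tcpca.fit_tcpca(pair, 2.0, 0.0, m_feature=2, m_time=1)
        assert basis.time_basis.shape == (1, 1) and abs(basis.time_basis[0, 0]) == 1.0
        # direct contrastive PCA on the N x k matrices
        xt = target.values[:, 0, :]
        xb = background.values[:, 0, :]
        ct = np.cov(xt, rowvar=False, bias=True)
        cb = np.cov(xb, rowvar=False, bias=True)
        eigvals, eigvecs = np.linalg.eigh(ct - 2.0 * cb)
        ref = eigvecs[:, np.argsort(-eigvals)[:2]]
        overlap = np.abs(np.diag(ref.T @ basis.feature_basis))
        np.testing.assert_allclose(overlap, 1.0, atol=1e-8)

    def test_planted_axes_recovered(self, planted):
        pair, truth = planted
        contrast = tcpca.fit_tcpca(pair, 50.0, 50.0, m_feature=1, m_time=1)
        plain = tcpca.fit_tcpca(pair, 0.0, 0.0, m_feature=1, m_time=1)
        cos_disease = abs(
            contrast.feature_basis[:, 0] @ truth.disease_feature_axes[:, 0]
        )
        cos_aging = abs(plain.feature_basis[:, 0] @ truth.aging_feature_axes[:, 0])
        assert cos_disease > 0.95
        assert cos_aging > 0.95

    def test_ablation_modes_use_identity_bases(self, tiny_pair):
        f_only = tcpca.fit_tcpca(tiny_pair, 0.5, 0.5, m_feature=1, mode="feature_only")
        np.testing.assert_array_equal(f_only.time_basis, np.eye(2))
        t_only = tcpca.fit_tcpca(tiny_pair, 0.5, 0.5, m_time=1, mode="time_only")
        np.testing.assert_array_equal(t_only.feature_basis, np.eye(2))

    def test_excessive_rank_rejected(self, tiny_pair):
        with pytest.raises(ValueError, match="m_feature"):
            tcpca.fit_tcpca(tiny_pair, 0.0, 0.0, m_feature=3, m_time=1)


class TestTransform:
    def test_identity_bases_return_input(self, tiny_pair):
        basis = tcpca.ContrastiveBasis(
            feature_basis=np.eye(2),
            time_basis=np.eye(2),
            eigvals_feature=None,
            eigvals_time=None,
            alpha_feature=0.0,
            alpha_time=0.0,
            mode="full",
        )
        rep = tcpca.transform(basis, tiny_pair.target)
        np.testing.assert_array_equal(rep.matrices, tiny_pair.target.values)

    def test_rank_one_projection_is_bilinear_form(self, tiny_pair):
        basis = tcpca.fit_tcpca(tiny_pair, 0.3, 0.3, m_feature=1, m_time=1)
        rep = tcpca.transform(basis, tiny_pair.target)
        u = basis.time_basis[:, 0]
        v = basis.feature_basis[:, 0]
        for i, s in enumerate(tiny_pair.target.values):
            expected = sum(
                u[t] * s[t, f] * v[f]
                for t in range(s.shape[0])
                for f in range(s.shape[1])
            )
            assert abs(rep.matrices[i, 0, 0] - expected) < 1e-10

    def test_projection_is_linear(self, tiny_pair, rng_factory):
        rng = rng_factory(0)
        basis = tcpca.fit_tcpca(tiny_pair, 0.3, 0.3, m_feature=2, m_time=2)
        s1 = make_cohort(rng.normal(size=(3, 2, 2)))
        s2 = make_cohort(rng.normal(size=(3, 2, 2)))
        combo = make_cohort(2.0 * s1.values - 0.5 * s2.values)
        lhs = tcpca.transform(basis, combo).matrices
        rhs = (
            2.0 * tcpca.transform(basis, s1).matrices
            - 0.5 * tcpca.transform(basis, s2).matrices
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_full_rank_projection_preserves_frobenius_norm(self, tiny_pair):
        basis = tcpca.fit_tcpca(tiny_pair, 0.3, 0.3, m_feature=2, m_time=2)
        rep = tcpca.transform(basis, tiny_pair.target)
        np.testing.assert_allclose(
            np.linalg.norm(rep.matrices, axis=(1, 2)),
            np.linalg.norm(tiny_pair.target.values, axis=(1, 2)),
            atol=1e-10,
        )

    def test_flat_view_is_row_major(self, tiny_pair):
        basis = tcpca.fit_tcpca(tiny_pair, 0.3, 0.3, m_feature=2, m_time=2)
        rep = tcpca.transform(basis, tiny_pair.target)
        np.testing.assert_array_equal(rep.flat[0], rep.matrices[0].ravel(order="C"))

    def test_shape_mismatch_rejected(self, tiny_pair, planted):
        basis = tcpca.fit_tcpca(tiny_pair, 0.3, 0.3, m_feature=2, m_time=2)
        pair, _ = planted
        with pytest.raises(ValueError, match="do not match"):
            tcpca.transform(basis, pair.target)


class TestSelectRanks:
    def _cov(self, spectrum):
        d = len(spectrum)
        return tcpca.ContrastiveCovariance(
            axis="feature",
            c_target=np.diag(np.asarray(spectrum, dtype=float)),
            c_background=np.zeros((d, d)),
            alpha=0.0,
        )

    def test_dominant_eigenvalue_suffices(self):
        assert _rank_by_energy(self._cov([9.0, 1.0, -3.0]), 0.9) == 1

    def test_split_spectrum_needs_both(self):
        assert _rank_by_energy(self._cov([5.0, 5.0]), 0.99) == 2

    def test_minimality_against_exhaustive_scan(self, rng_factory):
        rng = rng_factory(11)
        for _ in range(20):
            spec = rng.normal(size=6) * rng.uniform(0.5, 5)
            cov = self._cov(spec)
            if not np.any(spec > 0):
                with pytest.raises(ValueError):
                    _rank_by_energy(cov, 0.8)
                continue
            m = _rank_by_energy(cov, 0.8)
            pos = np.sort(spec[spec > 0])[::-1]
            feasible = [
                j + 1
                for j in range(len(pos))
                if pos[: j + 1].sum() >= 0.8 * pos.sum() - 1e-12
            ]
            assert m == min(feasible)

    def test_no_positive_eigenvalue_is_an_error(self):
        with pytest.raises(ValueError, match="no positive eigenvalue"):
            _rank_by_energy(self._cov([-1.0, -2.0]), 0.9)


class TestContrastProperties:
    def test_top_direction_maximizes_contrastive_variance(self, planted, rng_factory):
        pair, _ = planted
        cov = tcpca.contrastive_covariance(pair, "feature", 5.0)
        basis, eigvals = tcpca.top_contrastive_directions(cov, 1)
        v = basis[:, 0]
        top = v @ cov.combined @ v
        assert abs(top - eigvals[0]) < 1e-8
        rng = rng_factory(2)
        for _ in range(200):
            w = rng.normal(size=v.size)
            w /= np.linalg.norm(w)
            assert w @ cov.combined @ w <= top + 1e-8

    def test_background_variance_suppression_monotone_in_alpha(self, planted):
        pair, _ = planted
        cov_b = tcpca.contrastive_covariance(pair, "feature", 0.0).c_background
        captured = []
        for alpha in [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0]:
            cov = tcpca.contrastive_covariance(pair, "feature", alpha)
            v = tcpca.top_contrastive_directions(cov, 1)[0][:, 0]
            captured.append(v @ cov_b @ v)
        assert all(b <= a + 1e-8 for a, b in zip(captured, captured[1:]))
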