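"""Direct-method fitting: QR pruning, least-squares equivalence, residuals."""

import numpy as np
import pytest

from sanod import (
    ComponentSet,
    Dataset,
    MockConfig,
    SpectralAxis,
    TimeAxis,
    generate_mock_trxl,
    lcf_fit,
    lcf_fit_weighted,
    qr_orthonormalize,
    residual_summary,
)
from sanod.metrics import r_squared
from conftest import random_components, random_dataset


def axis_of(n):
    return SpectralAxis(np.arange(n, dtype=float))


def comp_set(matrix, labels=None):
    n, k = matrix.shape
    labels = labels or tuple(f"c{i}" for i in range(k))
    return ComponentSet(axis_of(n), matrix, labels, tuple("prior" for _ in range(k)))


class TestOrthonormalize:
    def test_orthonormal_inputs_kept_unchanged(self):
        m = np.zeros((4, 2))
        m[0, 0] = 1.0
        m[2, 1] = 1.0
        basis = qr_orthonormalize(comp_set(m))
        assert basis.retained_indices == (0, 1)
        assert all(r.remainder_fraction == pytest.approx(1.0) for r in basis.report.records)
        assert np.allclose(np.abs(basis.ortho), m)

    def test_exact_linear_combination_flagged(self, rng):
        v1 = rng.normal(size=30)
        v2 = rng.normal(size=30)
        v3 = 0.5 * v1 + 0.5 * v2
        v3 *= 1 + 1e-8 * rng.normal(size=30)
        basis = qr_orthonormalize(comp_set(np.column_stack([v1, v2, v3])))
        rec = basis.report.records[2]
        assert rec.flagged
        assert rec.remainder_fraction < 1e-6
        assert basis.retained_indices == (0, 1)

    def test_factorization_identities(self, rng):
        comps = comp_set(rng.normal(size=(25, 5)))
        basis = qr_orthonormalize(comps)
        assert np.allclose(basis.ortho.T @ basis.ortho, np.eye(5), atol=1e-10)
        assert np.allclose(basis.ortho @ basis.rmatrix, comps.matrix, atol=1e-10)

    def test_collinear_pair_keeps_first_only(self):
        # the first component can never be flagged (its remainder is itself)
        v = np.arange(1.0, 7.0)
        basis = qr_orthonormalize(comp_set(np.column_stack([v, 2 * v]), ("a", "b")), dep_tol=0.5)
        assert basis.retained_indices == (0,)
        assert basis.report.flagged_labels == ("b",)

    def test_no_components_errors(self):
        from sanod import ComponentSet

        with pytest.raises(ValueError, match="no components"):
            qr_orthonormalize(ComponentSet.empty(axis_of(5)))

    def test_bad_tolerance_rejected(self, rng):
        with pytest.raises(ValueError, match="dep_tol"):
            qr_orthonormalize(comp_set(rng.normal(size=(5, 2))), dep_tol=1.5)


class TestUnweightedFit:
    def test_exact_span_membership(self, rng):
        C = rng.normal(size=(20, 2))
        y = 2.0 * C[:, 0] - 1.0 * C[:, 1]
        ds = Dataset(axis_of(20), TimeAxis(np.array([0.0])), y[:, None])
        fit = lcf_fit(ds, comp_set(C))
        assert np.allclose(fit.chronograms.weights[:, 0], [2.0, -1.0], atol=1e-10)
        assert np.max(np.abs(fit.residual)) < 1e-10

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pseudo_inverse(self, trial):
        rng = np.random.default_rng(200 + trial)
        ds = random_dataset(rng, n=40, t=15, with_sigma=False)
        comps = random_components(rng, ds.axis, 4)
        fit = lcf_fit(ds, comps)
        oracle = np.linalg.pinv(comps.matrix) @ ds.signal
        assert np.max(np.abs(fit.chronograms.weights - oracle)) < 1e-8 * np.max(np.abs(oracle))

    def test_residual_orthogonal_to_components(self, rng):
        ds = random_dataset(rng, n=30, t=8, with_sigma=False)
        comps = random_components(rng, ds.axis, 3)
        fit = lcf_fit(ds, comps)
        dots = comps.matrix.T @ fit.residual
        scale = np.linalg.norm(comps.matrix, axis=0)[:, None] * np.linalg.norm(fit.residual, axis=0)
        assert np.max(np.abs(dots) / np.maximum(scale, 1e-300)) < 1e-8

    def test_reconstruction_identity(self, rng):
        ds = random_dataset(rng, n=30, t=8, with_sigma=False)
        comps = random_components(rng, ds.axis, 3)
        fit = lcf_fit(ds, comps)
        err = np.max(np.abs(fit.reconstructed + fit.residual - ds.signal))
        assert err <= 1e-12 * np.max(np.abs(ds.signal))

    def test_basis_invariance(self, rng):
        ds = random_dataset(rng, n=30, t=8, with_sigma=False)
        comps = random_components(rng, ds.axis, 3)
        fit_a = lcf_fit(ds, comps)
        mix = np.array([[1.0, 0.3, -0.2], [0.0, 1.1, 0.4], [0.2, 0.0, 0.9]])
        comps_b = ComponentSet(ds.axis, comps.matrix @ mix, comps.labels, comps.provenance)
        fit_b = lcf_fit(ds, comps_b)
        assert np.allclose(fit_a.reconstructed, fit_b.reconstructed, atol=1e-8)
        assert np.allclose(fit_a.residual, fit_b.residual, atol=1e-8)

    def test_flagged_component_gets_zero_weight(self, rng):
        v1, v2 = rng.normal(size=30), rng.normal(size=30)
        comps = comp_set(np.column_stack([v1, v2, v1 + v2]))
        ds = Dataset(axis_of(30), TimeAxis(np.arange(5.0)), rng.normal(size=(30, 5)))
        with pytest.warns(UserWarning, match="discarded"):
            fit = lcf_fit(ds, comps)
        assert np.array_equal(fit.chronograms.weights[2], np.zeros(5))
        assert fit.n_retained == 2

    def test_omission_never_decreases_misfit(self, rng):
        ds, truth = generate_mock_trxl(MockConfig(seed=11))
        full = lcf_fit(ds, truth.components)
        for drop in truth.components.labels:
            keep = [l for l in truth.components.labels if l != drop]
            part = lcf_fit(ds, truth.components.subset(keep))
            assert part.total_misfit >= full.total_misfit


class TestWeightedFit:
    def test_uniform_sigma_degenerates_to_unweighted(self, rng):
        ds0 = random_dataset(rng, n=25, t=6, with_sigma=False)
        ds = Dataset(ds0.axis, ds0.times, ds0.signal, np.full_like(ds0.signal, 1.7))
        comps = random_components(rng, ds.axis, 3)
        w = lcf_fit_weighted(ds, comps).chronograms.weights
        u = lcf_fit(ds, comps).chronograms.weights
        assert np.allclose(w, u, atol=1e-10)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_weighted_normal_equations(self, trial):
        rng = np.random.default_rng(300 + trial)
        ds = random_dataset(rng, n=30, t=8, with_sigma=True)
        comps = random_components(rng, ds.axis, 4)
        fit = lcf_fit_weighted(ds, comps)
        C = comps.matrix
        for t in range(ds.n_time):
            w = 1.0 / ds.sigma[:, t] ** 2
            oracle = np.linalg.solve(C.T @ (C * w[:, None]), C.T @ (ds.signal[:, t] * w))
            assert np.max(np.abs(fit.chronograms.weights[:, t] - oracle)) < 1e-8 * max(
                1e-12, np.max(np.abs(oracle))
            )

    def test_outlier_down_weighted(self, rng):
        n = 30
        C = rng.normal(size=(n, 1))
        y = 2.0 * C[:, 0]
        y[5] += 100.0
        sigma = np.ones((n, 1))
        sigma[5, 0] = 1e4
        ds = Dataset(axis_of(n), TimeAxis(np.array([0.0])), y[:, None], sigma)
        comps = comp_set(C, ("c0",))
        w_weighted = lcf_fit_weighted(ds, comps).chronograms.weights[0, 0]
        w_plain = lcf_fit(ds, comps).chronograms.weights[0, 0]
        assert abs(w_weighted - 2.0) < 1e-3
        assert abs(w_plain - 2.0) > 10 * abs(w_weighted - 2.0)

    def test_missing_sigma_rejected(self, rng):
        ds = random_dataset(rng, n=10, t=3, with_sigma=False)
        with pytest.raises(ValueError, match="sigma"):
            lcf_fit_weighted(ds, random_components(rng, ds.axis, 2))


class TestResidualSummary:
    def test_zero_residual_gives_zero_misfit(self, rng):
        C = rng.normal(size=(20, 2))
        weights = rng.normal(size=(2, 6))
        ds = Dataset(axis_of(20), TimeAxis(np.arange(6.0)), C @ weights)
        table = residual_summary(lcf_fit(ds, comp_set(C)))
        assert np.allclose(table["misfit"], 0.0, atol=1e-18)

    def test_reduced_chi_square_calibrated(self):
        # sigma equals the true noise level, so chi2/dof should be ~1
        values = []
        for seed in range(5):
            ds, truth = generate_mock_trxl(MockConfig(seed=seed))
            fit = lcf_fit_weighted(ds, truth.components)
            values.append(residual_summary(fit)["reduced_chi2"].mean())
        assert 0.8 <= np.mean(values) <= 1.2

    def test_overparameterized_fit_rejected(self, rng):
        ds = random_dataset(rng, n=4, t=3, with_sigma=False)
        comps = random_components(rng, ds.axis, 4)
        with pytest.raises(ValueError, match="degrees of freedom"):
            residual_summary(lcf_fit(ds, comps))


class TestChronogramRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_true_components_recover_true_chronograms(self, seed):
        ds, truth = generate_mock_trxl(MockConfig(seed=seed))
        fit = lcf_fit(ds, truth.components)
        for label in truth.components.labels:
            assert r_squared(truth.chronograms.row(label), fit.chronograms.row(label)) >= 0.99
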