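"""APGD solver: prox operators, step size, convergence, rescaling."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cset.forward import LeadField, SensorRecording
from cset.graph import SpectralBasis
from cset.solver import (
    SolverConfig,
    apgd_solve,
    lipschitz_step,
    objective,
    prox_spectral_l1,
    rescale_solution,
    soft_threshold,
    solve_cset,
)


def random_orthonormal(n, rng):
    return scipy.stats.ortho_group.rvs(n, random_state=rng)


def ista_oracle(B, b, lam, n_iter=100_000):
    """Plain proximal gradient descent in the spectral coordinates,
    independent of the accelerated implementation."""
    smax = np.linalg.svd(B, compute_uv=False)[0]
    tau = 1.0 / (2.0 * smax**2)
    c = np.zeros(B.shape[1])
    for _ in range(n_iter):
        g = 2.0 * B.T @ (B @ c - b)
        z = c - tau * g
        c = np.sign(z) * np.maximum(np.abs(z) - tau * lam, 0.0)
    return c


class TestObjective:
    def test_zero_solution_gives_data_norm(self, rng):
        A = rng.normal(size=(4, 6))
        b = rng.normal(size=4)
        U = np.eye(6)
        assert objective(A, b, U, 0.3, np.zeros(6)) == pytest.approx(b @ b)

    def test_exact_solution_zero_when_unpenalized(self, rng):
        A = rng.normal(size=(5, 5)) + 3 * np.eye(5)
        x = rng.normal(size=5)
        assert objective(A, A @ x, np.eye(5), 0.0, x) == pytest.approx(0.0, abs=1e-18)

    def test_matches_termwise_evaluation(self, rng):
        A = rng.normal(size=(6, 9))
        b = rng.normal(size=6)
        U = random_orthonormal(9, rng)
        x = rng.normal(size=9)
        lam = 0.7
        resid = sum((b[i] - np.dot(A[i], x)) ** 2 for i in range(6))
        penalty = lam * sum(abs(np.dot(U[:, l], x)) for l in range(9))
        assert objective(A, b, U, lam, x) == pytest.approx(resid + penalty, rel=1e-12)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z,tau,expected",
        [(2.5, 1.0, 1.5), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (0.4, 0.0, 0.4)],
    )
    def test_formula(self, z, tau, expected):
        assert soft_threshold(np.array([z]), tau)[0] == pytest.approx(expected)

    def test_matches_scalar_prox_grid_search(self, rng):
        # S_tau(z) is the minimizer of 0.5 (u - z)^2 + tau |u|
        z = rng.normal(scale=2.0, size=20)
        tau = 0.8
        out = soft_threshold(z, tau)
        for zi, oi in zip(z, out):
            grid = np.linspace(-abs(zi) - 1, abs(zi) + 1, 400_001)
            vals = 0.5 * (grid - zi) ** 2 + tau * np.abs(grid)
            assert abs(grid[np.argmin(vals)] - oi) < 1e-4

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        z=hnp.arrays(np.float64, st.integers(1, 20),
                     elements=st.floats(-1e6, 1e6)),
        tau=st.floats(0.0, 1e3),
    )
    def test_shrinkage_properties(self, z, tau):
        out = soft_threshold(z, tau)
        # magnitudes shrink by exactly tau (floored at zero), signs preserved
        np.testing.assert_allclose(np.abs(out),
                                   np.maximum(np.abs(z) - tau, 0.0))
        assert np.all((out == 0) | (np.sign(out) == np.sign(z)))
        # non-expansive map
        assert np.all(np.abs(out) <= np.abs(z))


class TestProxSpectralL1:
    def test_identity_basis_reduces_to_soft_threshold(self, rng):
        z = rng.normal(size=8)
        np.testing.assert_allclose(
            prox_spectral_l1(np.eye(8), z, 0.5), soft_threshold(z, 0.5), atol=1e-12
        )

    def test_zero_threshold_is_identity(self, rng):
        U = random_orthonormal(6, rng)
        z = rng.normal(size=6)
        np.testing.assert_allclose(prox_spectral_l1(U, z, 0.0), z, atol=1e-12)

    def test_matches_convex_oracle(self, rng):
        # exact prox via change of variables + per-coordinate scalar prox
        for _ in range(20):
            n = int(rng.integers(6, 11))
            U = random_orthonormal(n, rng)
            z = rng.normal(size=n)
            tau = float(rng.uniform(0.1, 1.0))
            out = prox_spectral_l1(U, z, tau)
            w = U.T @ z
            u_star = np.sign(w) * np.maximum(np.abs(w) - tau, 0.0)
            x_star = U @ u_star

            def F(x):
                return 0.5 * np.sum((x - z) ** 2) + tau * np.abs(U.T @ x).sum()

            assert F(out) - F(x_star) < 1e-8

    def test_non_orthonormal_rejected(self, rng):
        U = rng.normal(size=(5, 5))
        with pytest.raises(ValueError, match="orthonormal"):
            prox_spectral_l1(U, np.zeros(5), 0.1)


class TestLipschitzStep:
    def test_identity(self):
        rho, tau = lipschitz_step(np.eye(4))
        assert rho == pytest.approx(2.0)
        assert tau == pytest.approx(0.5)

    def test_scalar_matrix(self):
        rho, _ = lipschitz_step(np.array([[3.0]]))
        assert rho == pytest.approx(18.0)

    def test_matches_dense_gram_eigenvalue(self, rng):
        A = rng.normal(size=(8, 20))
        rho, _ = lipschitz_step(A)
        lmax = np.linalg.eigvalsh(A.T @ A).max()
        assert rho / 2 == pytest.approx(lmax, rel=1e-8)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            lipschitz_step(np.zeros((3, 3)))


class TestApgdSolve:
    def test_zero_data_gives_zero_solution(self, rng):
        A = rng.normal(size=(5, 12))
        res = apgd_solve(A, np.zeros(5), np.eye(12), SolverConfig(lam=0.3))
        np.testing.assert_array_equal(res.x_hat, np.zeros(12))

    def test_identity_closed_form(self, rng):
        # A = I, U = I: minimizer of ||b - x||^2 + lam ||x||_1 is S_{lam/2}(b)
        for _ in range(5):
            b = rng.normal(size=10)
            lam = float(rng.uniform(0.1, 1.0))
            res = apgd_solve(np.eye(10), b, np.eye(10),
                             SolverConfig(lam=lam, tol=1e-10, max_iter=5000))
            np.testing.assert_allclose(res.x_hat, soft_threshold(b, lam / 2),
                                       atol=1e-6)

    def test_matches_long_ista_run(self, rng):
        A = rng.normal(size=(10, 30))
        U = random_orthonormal(30, rng)
        b = rng.normal(size=10)
        lam = 0.1
        res = apgd_solve(A, b, U, SolverConfig(lam=lam, tol=1e-10, max_iter=20_000))
        c_oracle = ista_oracle(A @ U, b, lam)
        f_apgd = objective(A, b, U, lam, res.x_hat)
        f_oracle = objective(A, b, U, lam, U @ c_oracle)
        assert f_apgd <= f_oracle + 1e-6 * abs(f_oracle)

    def test_lam_zero_matches_min_norm_least_squares(self, rng):
        for m, n in [(20, 8), (8, 20)]:  # over- and under-determined
            A = rng.normal(size=(m, n))
            b = rng.normal(size=m)
            U = random_orthonormal(n, rng)
            res = apgd_solve(A, b, U, SolverConfig(lam=0.0, tol=1e-12,
                                                   max_iter=50_000))
            x_pinv = np.linalg.pinv(A) @ b
            err = np.linalg.norm(res.x_hat - x_pinv) / np.linalg.norm(x_pinv)
            assert err < 1e-4

    def test_fixed_point_of_returned_solution(self, rng):
        A = rng.normal(size=(8, 16))
        U = random_orthonormal(16, rng)
        b = rng.normal(size=8)
        cfg = SolverConfig(lam=0.2, tol=1e-6, max_iter=50_000)
        res = apgd_solve(A, b, U, cfg)
        assert bool(res.converged[0])
        # one further (non-accelerated) prox-gradient step barely moves x
        _, tau = lipschitz_step(A)
        x = res.x_hat
        z = x - tau * 2.0 * A.T @ (A @ x - b)
        x2 = prox_spectral_l1(U, z, tau * cfg.lam)
        assert np.linalg.norm(x2 - x) / np.linalg.norm(x) < 10 * cfg.tol

    def test_objective_trace_decreases_overall(self, rng):
        A = rng.normal(size=(6, 15))
        U = random_orthonormal(15, rng)
        b = rng.normal(size=6)
        res = apgd_solve(A, b, U, SolverConfig(lam=0.1))
        assert res.objective_trace[-1] <= res.objective_trace[0]

    def test_max_iter_flags_not_converged(self, rng):
        A = rng.normal(size=(6, 15))
        b = rng.normal(size=6)
        res = apgd_solve(A, b, np.eye(15), SolverConfig(lam=0.01, tol=1e-14,
                                                        max_iter=5))
        assert not bool(res.converged[0])
        assert int(res.n_iter[0]) == 5

    def test_sparsity_nonincreasing_in_lambda_in_aggregate(self, rng):
        # median active-coefficient count over 10 seeds is non-increasing
        # along the regularization grid
        grid = np.logspace(-5, np.log10(0.3), 20)
        counts = np.zeros((10, grid.size))
        for s in range(10):
            srng = np.random.default_rng(1000 + s)
            A = srng.normal(size=(10, 30))
            U = random_orthonormal(30, srng)
            b = srng.normal(size=10)
            for k, lam in enumerate(grid):
                res = apgd_solve(A, b, U, SolverConfig(lam=float(lam)))
                c = U.T @ res.x_hat
                counts[s, k] = np.sum(np.abs(c) > 1e-8)
        med = np.median(counts, axis=0)
        assert np.all(np.diff(med) <= 0 + 1e-9)


class TestRescaleSolution:
    def test_identity_under_unit_factors(self, rng):
        x = rng.normal(size=9)
        np.testing.assert_allclose(rescale_solution(x, np.ones(9), 1.0), x)

    def test_linear_in_b_scale(self, rng):
        x = rng.normal(size=9)
        norms = rng.uniform(0.5, 2.0, size=9)
        a = rescale_solution(x, norms, 2.0)
        b = rescale_solution(x, norms, 4.0)
        np.testing.assert_allclose(b, 2 * a, rtol=1e-15)

    def test_pipeline_homogeneity(self, small_signed_scenario):
        # scaling the raw recording by 7 scales the reconstruction by 7
        sc = small_signed_scenario
        cfg = SolverConfig(lam=0.05)
        r1 = solve_cset(sc.leadfield, sc.recording, sc.basis, cfg)
        scaled = SensorRecording(b=7.0 * sc.recording.b,
                                 montage_ids=sc.recording.montage_ids)
        r7 = solve_cset(sc.leadfield, scaled, sc.basis, cfg)
        np.testing.assert_allclose(r7.x_hat, 7.0 * r1.x_hat, rtol=1e-12,
                                   atol=1e-12 * np.abs(r1.x_hat).max())

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            rescale_solution(np.ones(3), np.array([1.0, 0.0, 1.0]), 1.0)
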