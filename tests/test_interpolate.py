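import numpy as np
import pytest

import latgraph as lg
from latgraph.interpolate import SpectralDecomposition

from .conftest import random_problem, random_surface_graph


def dense_solve(problem, config):
    """Independent dense oracle for the closed-form solution."""
    n = problem.graph.n
    lap = problem.graph.laplacian.toarray()
    diag = np.where(problem.labeled_mask, 1.0, config.alpha)
    return np.linalg.solve(np.diag(diag) + config.beta * lap, problem.f_s)


class TestClosedFormSolver:
    def test_fully_labeled_beta_zero_is_identity(self):
        rng = np.random.default_rng(0)
        graph = random_surface_graph(rng, 30)
        f_s = rng.normal(-100, 30, 30)
        problem = lg.InterpolationProblem(graph, f_s, np.ones(30, dtype=bool))
        out = lg.graph_interpolate(problem, lg.InterpConfig(alpha=1e-5, beta=0.0))
        assert np.abs(out - f_s).max() <= 1e-12

    def test_two_vertex_example(self):
        # one edge of weight 1, only vertex 0 labeled at 10 ms
        graph = lg.SurfaceGraph(2, np.array([[0, 1]])).with_weights(np.array([1.0]))
        problem = lg.InterpolationProblem(
            graph, np.array([10.0, 0.0]), np.array([True, False])
        )
        out = lg.graph_interpolate(problem, lg.InterpConfig(alpha=1e-5, beta=1e-2))
        assert out == pytest.approx([9.99990, 9.98991], abs=5e-5)
        assert np.abs(out - dense_solve(problem, lg.InterpConfig())).max() <= 1e-12

    def test_zero_signal_gives_zero(self):
        rng = np.random.default_rng(1)
        graph = random_surface_graph(rng, 40)
        mask = np.zeros(40, dtype=bool)
        mask[:10] = True
        problem = lg.InterpolationProblem(graph, np.zeros(40), mask)
        assert np.abs(lg.graph_interpolate(problem)).max() == 0.0

    def test_linearity_in_signal(self):
        rng = np.random.default_rng(2)
        graph = random_surface_graph(rng, 60)
        mask = rng.random(60) < 0.5
        mask[0] = True
        u = np.where(mask, rng.normal(0, 50, 60), 0.0)
        v = np.where(mask, rng.normal(0, 50, 60), 0.0)
        cfg = lg.InterpConfig()
        fu = lg.graph_interpolate(lg.InterpolationProblem(graph, u, mask), cfg)
        fv = lg.graph_interpolate(lg.InterpolationProblem(graph, v, mask), cfg)
        fuv = lg.graph_interpolate(
            lg.InterpolationProblem(graph, 2.0 * u - 3.0 * v, mask), cfg
        )
        scale = np.abs(fuv).max()
        assert np.abs(fuv - (2.0 * fu - 3.0 * fv)).max() <= 1e-9 * scale

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            problem = random_problem(rng, int(rng.integers(5, 120)))
            cfg = lg.InterpConfig(
                alpha=float(10 ** rng.uniform(-5, 0)), beta=float(10 ** rng.uniform(-3, 0))
            )
            out = lg.graph_interpolate(problem, cfg)
            ref = dense_solve(problem, cfg)
            assert np.abs(out - ref).max() <= 1e-9 * max(np.abs(ref).max(), 1.0)

    def test_system_matrix_positive_definite(self):
        rng = np.random.default_rng(4)
        problem = random_problem(rng, 50)
        cfg = lg.InterpConfig(alpha=1e-3, beta=0.5)
        eig = np.linalg.eigvalsh(problem.system_matrix(cfg).toarray())
        assert eig.min() >= min(1.0, cfg.alpha) - 1e-12


class TestSpectralPath:
    def test_identity_filter(self):
        rng = np.random.default_rng(5)
        problem = random_problem(rng, 40)
        dec = SpectralDecomposition.from_graph(problem.graph)
        out = lg.spectral_interpolate(problem, dec, lambda lam: np.ones_like(lam))
        assert np.abs(out - problem.f_s).max() <= 1e-8 * max(np.abs(problem.f_s).max(), 1)

    def test_constant_fully_labeled_signal(self):
        rng = np.random.default_rng(6)
        graph = random_surface_graph(rng, 30)
        problem = lg.InterpolationProblem(
            graph, np.full(30, 7.0), np.ones(30, dtype=bool)
        )
        dec = SpectralDecomposition.from_graph(graph)
        out = lg.spectral_interpolate(problem, dec, lambda lam: 1.0 / (1.0 + lam))
        # constant = lambda_0 = 0 eigenvector; gain at 0 is 1
        assert np.abs(out - 7.0).max() <= 1e-6

    def test_equivalence_with_unit_regularisation(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            problem = random_problem(rng, int(rng.integers(10, 150)))
            direct = lg.graph_interpolate(problem, lg.InterpConfig(alpha=1.0, beta=1.0))
            dec = SpectralDecomposition.from_graph(problem.graph)
            spect = lg.spectral_interpolate(problem, dec, lambda lam: 1.0 / (1.0 + lam))
            assert np.abs(direct - spect).max() <= 1e-6 * max(np.abs(direct).max(), 1)

    def test_orthonormality_and_reconstruction(self):
        rng = np.random.default_rng(8)
        graph = random_surface_graph(rng, 50)
        dec = SpectralDecomposition.from_graph(graph)
        u = dec.eigenvectors
        assert np.abs(u.T @ u - np.eye(50)).max() <= 1e-8
        recon = u @ np.diag(dec.eigenvalues) @ u.T
        lap = graph.laplacian.toarray()
        assert np.abs(recon - lap).max() <= 1e-6 * max(np.abs(lap).max(), 1)


class TestGPRBaseline:
    def test_interpolates_training_points(self):
        rng = np.random.default_rng(9)
        xt = rng.normal(0, 1, (25, 3))
        yt = rng.normal(-100, 30, 25)
        pred = lg.gpr_baseline(xt, yt, xt, jitter=1e-12, rescale=False)
        assert np.abs(pred - yt).max() <= 1e-4

    def test_far_query_reverts_to_prior_mean(self):
        rng = np.random.default_rng(10)
        xt = rng.normal(0, 0.1, (10, 3))
        yt = rng.normal(50, 10, 10)
        far = np.array([[100.0, 100.0, 100.0]])
        pred = lg.gpr_baseline(xt, yt, far, rescale=False)
        assert np.abs(pred).max() <= 1e-6 * np.abs(yt).max()

    def test_single_point_closed_form(self):
        x = np.array([[0.1, 0.0, 0.0]])
        y = np.array([12.0])
        q = np.array([[0.15, 0.0, 0.0]])
        jitter = 1e-8
        ls = (0.01, 0.1, 1.0)
        k_qx = sum(np.exp(-0.05**2 / (2 * ell**2)) for ell in ls)
        k_xx = 3.0 + jitter
        expected = 12.0 * k_qx / k_xx
        pred = lg.gpr_baseline(x, y, q, jitter=jitter, rescale=False)
        assert pred[0] == pytest.approx(expected, rel=1e-10)

    def test_duplicate_training_points_merged(self):
        x = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        y = np.array([10.0, 20.0, 5.0])
        pred = lg.gpr_baseline(x, y, np.array([[0.0, 0.0, 0.0]]), rescale=False)
        merged = lg.gpr_baseline(
            np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
            np.array([15.0, 5.0]),
            np.array([[0.0, 0.0, 0.0]]),
            rescale=False,
        )
        assert pred[0] == pytest.approx(merged[0], rel=1e-12)

    def test_matches_reference_gp(self):
        """Cross-check against an established GP implementation."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF

        rng = np.random.default_rng(11)
        xt = rng.normal(0, 0.5, (30, 3))
        yt = rng.normal(0, 20, 30)
        xq = rng.normal(0, 0.5, (8, 3))
        ours = lg.gpr_baseline(xt, yt, xq, rescale=False)
        kernel = RBF(0.01) + RBF(0.1) + RBF(1.0)
        ref = (
            GaussianProcessRegressor(kernel=kernel, alpha=1e-8, optimizer=None)
            .fit(xt, yt)
            .predict(xq)
        )
        assert np.abs(ours - ref).max() <= 1e-8 * max(np.abs(ref).max(), 1)
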