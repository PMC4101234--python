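"""ART, the Split-Bregman two-loop solvers and their building blocks."""

import numpy as np
import pytest
import scipy.sparse as sp

import nactct as n
from nactct.geometry_sim import ProjectionGeometry, SystemMatrix
from nactct.reconstruct import SplitBregmanState, _reg_gradient


def tiny_system(matrix, n_detectors=1):
    """Wrap a dense matrix as a SystemMatrix with one view per row-block."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n_views = matrix.shape[0] // n_detectors
    size = int(np.sqrt(matrix.shape[1]))
    geom = ProjectionGeometry(angles=np.arange(n_views, dtype=float),
                              n_detectors=n_detectors)
    return SystemMatrix(matrix=sp.csr_matrix(matrix), geometry=geom,
                        image_shape=(size, size))


class TestARTSweep:
    def test_single_row_projection(self):
        A = tiny_system([[1.0, 0.0, 0.0, 0.0]])
        f = n.art_sweep(np.zeros((2, 2)), A, np.array([[2.0]]))
        assert np.array_equal(f, np.array([[2.0, 0.0], [0.0, 0.0]]))

    def test_each_row_satisfied_after_its_update(self, small_setup, rng):
        """Kaczmarz projection property: the last-updated row fits exactly."""
        f, A, p = small_setup
        f1 = n.art_sweep(np.zeros(A.image_shape), A, p)
        last = A.matrix.shape[0] - 1
        row = A.matrix[last]
        assert (row @ f1.ravel()).item() == pytest.approx(p.ravel()[last],
                                                          abs=1e-10)

    def test_converges_to_exact_solution(self):
        """Repeated sweeps on a small consistent system reach the solution."""
        M = np.array([[2.0, 1.0, 0.0, 0.0],
                      [1.0, 3.0, 1.0, 0.0],
                      [0.0, 1.0, 2.0, 1.0],
                      [0.5, 0.0, 1.0, 2.0]])
        x_true = np.array([1.0, 2.0, 0.5, 1.5])
        p = (M @ x_true).reshape(4, 1)
        A = tiny_system(M)
        f = np.zeros((2, 2))
        for _ in range(1000):
            f = n.art_sweep(f, A, p)
        assert np.linalg.norm(M @ f.ravel() - p.ravel()) < 1e-8

    def test_zero_matrix_rejected(self):
        A = tiny_system(np.zeros((2, 4)), n_detectors=2)
        with pytest.raises(ValueError):
            n.art_sweep(np.zeros((2, 2)), A, np.zeros((1, 2)))


class TestPositivity:
    def test_clamps_negatives(self):
        f = np.array([[-1.0, 2.0], [0.0, -3.0]])
        assert np.array_equal(n.positivity(f), [[0.0, 2.0], [0.0, 0.0]])

    def test_nonnegative_unchanged_and_never_increases(self, rng):
        f = rng.random((4, 4))
        assert np.array_equal(n.positivity(f), f)
        g = rng.normal(size=(4, 4))
        assert np.all(n.positivity(g) >= g)


class TestARTReconstruct:
    def test_consistent_system_small_phantom(self):
        """Many sweeps on exact 8x8 data reach sub-1e-3 error."""
        size = 16
        f = n.make_phantom(size)
        geom = ProjectionGeometry(angles=n.make_angles(24), n_detectors=size)
        A = n.build_system_matrix(f.shape, geom)
        p = n.project(A, f)
        fr = n.art_reconstruct(A, p, n.ReconParams(n_outer=500))
        assert n.rmse(f, fr) < 5e-3

    def test_zero_sinogram_gives_zero_image(self, small_setup):
        _, A, _ = small_setup
        fr = n.art_reconstruct(A, np.zeros((A.geometry.n_views,
                                            A.geometry.n_detectors)),
                               n.ReconParams(n_outer=3))
        assert np.all(fr == 0.0)


class TestSpbrGradient:
    def test_reduces_to_data_gradient_without_regularization(self, rng):
        """With gamma=mu=0 the direction matches a finite-difference gradient
        of lambda ||A_m f - p_m||^2."""
        size = 4
        M = rng.random((8, size * size))
        A = tiny_system(M, n_detectors=4)
        p = rng.random((2, 4))
        f = rng.random((size, size))
        params = n.ReconParams(lambda_=3.0, gamma=0.0, mu=0.0)
        state = SplitBregmanState(dx=np.zeros_like(f), dy=np.zeros_like(f),
                                  bx=np.zeros_like(f), by=np.zeros_like(f))
        m = 1
        ghat = n.spbr_gradient(f, A, p, state, params, m)
        assert np.linalg.norm(ghat) == pytest.approx(1.0, rel=1e-12)

        def obj(x):
            r = A.view_block(m) @ x.ravel() - p[m]
            return params.lambda_ * float(r @ r)

        fd = np.zeros_like(f)
        h = 1e-6
        for i in range(size):
            for j in range(size):
                e = np.zeros_like(f)
                e[i, j] = h
                fd[i, j] = (obj(f + e) - obj(f - e)) / (2 * h)
        fd /= np.linalg.norm(fd)
        assert np.abs(ghat - fd).max() < 1e-5

    def test_zero_at_quadratic_stationary_point(self, rng):
        """At the exact minimizer of the TV-augmented quadratic subproblem the
        gradient vanishes (solved by normal equations on a 4x4 toy)."""
        size = 4
        npix = size * size
        M = rng.random((4, npix))
        A = tiny_system(M, n_detectors=4)
        lam, gam = 2.0, 1.5
        # dense backward-difference matrices (independent oracle)
        eye = np.eye(npix)
        Gx = np.stack([n.grad_x(e.reshape(size, size)).ravel() for e in eye],
                      axis=1)
        Gy = np.stack([n.grad_y(e.reshape(size, size)).ravel() for e in eye],
                      axis=1)
        dx = rng.normal(size=(size, size))
        dy = rng.normal(size=(size, size))
        bx = rng.normal(size=(size, size))
        by = rng.normal(size=(size, size))
        p_m = rng.random(4)
        # minimize lam||Mx - p||^2 + gam||dx - Gx x - bx||^2 + gam||dy - ...||^2
        H = lam * M.T @ M + gam * (Gx.T @ Gx + Gy.T @ Gy)
        rhs = (lam * M.T @ p_m + gam * Gx.T @ (dx - bx).ravel()
               + gam * Gy.T @ (dy - by).ravel())
        x_star = np.linalg.solve(H, rhs).reshape(size, size)
        params = n.ReconParams(lambda_=lam, gamma=gam, mu=0.0)
        state = SplitBregmanState(dx=dx, dy=dy, bx=bx, by=by)
        g = 2 * lam * (A.view_block(0).T @ (A.view_block(0) @ x_star.ravel()
                                            - p_m)).reshape(size, size)
        g += _reg_gradient(x_star, state, params, None)
        assert np.abs(g).max() < 1e-8

    def test_exactly_zero_gradient_returns_zero(self):
        """When the raw gradient vanishes the direction is zero, not 0/0."""
        size = 4
        A = tiny_system(np.zeros((4, size * size)) + np.eye(4, size * size),
                        n_detectors=4)
        f = np.zeros((size, size))
        params = n.ReconParams(lambda_=2.0, gamma=0.0, mu=0.0)
        state = SplitBregmanState(dx=f, dy=f, bx=f, by=f)
        ghat = n.spbr_gradient(f, A, np.zeros((1, 4)), state, params, 0)
        assert np.all(ghat == 0.0)


class TestTwoLoopSolvers:
    def test_zero_sinogram_fixed_point(self, small_setup):
        _, A, _ = small_setup
        zeros = np.zeros((A.geometry.n_views, A.geometry.n_detectors))
        params = n.ReconParams(n_outer=2)
        assert np.all(n.art_tv_reconstruct(A, zeros, params) == 0.0)
        t = n.NACT(levels=2, dirs_per_level=(4, 4))
        assert np.all(n.spbr_nact_reconstruct(A, zeros, params,
                                              transform=t) == 0.0)

    def test_output_nonnegative(self, small_setup):
        f, A, p = small_setup
        params = n.ReconParams(n_outer=2, k_inner=3)
        t = n.NACT(levels=2, dirs_per_level=(4, 4))
        fr = n.spbr_nact_reconstruct(A, p, params, transform=t)
        assert fr.min() >= 0.0

    def test_monotone_data_fidelity_noise_free(self, small_setup):
        f, A, p = small_setup
        residuals = []

        def cb(k, img):
            residuals.append(np.linalg.norm(A.matrix @ img.ravel()
                                            - p.ravel()))

        t = n.NACT(levels=2, dirs_per_level=(4, 4))
        n.spbr_nact_reconstruct(A, p, n.ReconParams(n_outer=8), transform=t,
                                callback=cb)
        r = np.array(residuals)
        assert np.all(r[1:] <= r[:-1] * 1.01)

    def test_stopping_rule_halts_outer_loop(self, small_setup):
        f, A, p = small_setup
        iterations = []
        # Residual after one ART pass is far below ||p||/2, so sigma at
        # that level stops the loop immediately after the first iteration.
        sigma = 0.5 * float(np.linalg.norm(p))
        params = n.ReconParams(n_outer=50, k_inner=1, sigma=sigma)
        t = n.NACT(levels=2, dirs_per_level=(4, 4))
        n.spbr_nact_reconstruct(A, p, params, transform=t,
                                callback=lambda k, img: iterations.append(k))
        assert iterations[-1] < 50

    def test_shrinkage_recursion_matches_reference(self, small_setup):
        """The inner d/b updates follow the Split-Bregman recursion: replay
        them independently from the recorded image sequence and compare the
        arguments actually passed to the shrinkage operator."""
        f, A, p = small_setup
        params = n.ReconParams(n_outer=1, k_inner=3, gamma=30.0, mu=0.0)

        from nactct import reconstruct as rec
        images, shrink_calls = [], []
        orig_pos, orig_shrink = rec.positivity, rec.shrink

        def pos_spy(x):
            out = orig_pos(x)
            images.append(np.array(out))
            return out

        def shrink_spy(x, t):
            shrink_calls.append((np.array(x), t))
            return orig_shrink(x, t)

        rec.positivity, rec.shrink = pos_spy, shrink_spy
        try:
            n.art_tv_reconstruct(A, p, params)
        finally:
            rec.positivity, rec.shrink = orig_pos, orig_shrink

        # One clamp after the ART pass, one per inner iteration; two shrink
        # calls (d_x, d_y) per inner iteration, all at threshold 1/lambda.
        assert len(images) == 1 + params.k_inner
        assert len(shrink_calls) == 2 * params.k_inner
        t_xy, _ = params.thresholds()
        assert all(t == t_xy for _, t in shrink_calls)

        # Replay: d = shrink(grad f + b, t); b <- b + grad f - d, from b = 0.
        bx = np.zeros_like(images[0])
        by = np.zeros_like(images[0])
        for k, img in enumerate(images[1:]):
            gx, gy = n.grad_x(img), n.grad_y(img)
            assert np.abs(shrink_calls[2 * k][0] - (gx + bx)).max() < 1e-12
            assert np.abs(shrink_calls[2 * k + 1][0] - (gy + by)).max() < 1e-12
            bx = bx + gx - orig_shrink(gx + bx, t_xy)
            by = by + gy - orig_shrink(gy + by, t_xy)

    def test_quality_ordering_small_scale(self):
        """At reduced scale the method ordering of the full study holds:
        contourlet+TV < TV-only < plain ART in RMSE, reversed in UQI."""
        size, nv = 64, 24
        f = n.make_phantom(size)
        geom = ProjectionGeometry(angles=n.make_angles(nv), n_detectors=size)
        A = n.build_system_matrix(f.shape, geom)
        p = n.project(A, f)
        params = n.ReconParams(n_outer=15, cache_regularization=True)
        fa = n.art_reconstruct(A, p, params)
        ft = n.art_tv_reconstruct(A, p, params)
        t = n.NACT(levels=3, dirs_per_level=(4, 8, 8))
        fs = n.spbr_nact_reconstruct(A, p, params, transform=t)
        assert n.rmse(f, fs) < n.rmse(f, ft) < n.rmse(f, fa)
        assert n.uqi(f, fs) > n.uqi(f, ft) > n.uqi(f, fa)

    def test_cached_regularization_close_to_exact(self):
        """Once-per-iteration caching of the regularization gradient changes
        the reconstruction only marginally at small scale."""
        size, nv = 32, 16
        f = n.make_phantom(size)
        geom = ProjectionGeometry(angles=n.make_angles(nv), n_detectors=size)
        A = n.build_system_matrix(f.shape, geom)
        p = n.project(A, f)
        t = n.NACT(levels=2, dirs_per_level=(4, 8))
        base = n.ReconParams(n_outer=10)
        cached = n.ReconParams(n_outer=10, cache_regularization=True)
        f_exact = n.spbr_nact_reconstruct(A, p, base, transform=t)
        f_cache = n.spbr_nact_reconstruct(A, p, cached, transform=t)
        assert abs(n.rmse(f, f_exact) - n.rmse(f, f_cache)) < 5e-3

    def test_divergence_guard(self):
        """Wildly inconsistent data with a huge step triggers the abort."""
        size = 8
        f = n.make_phantom(16)[:size, :size]
        geom = ProjectionGeometry(angles=n.make_angles(4), n_detectors=size)
        A = n.build_system_matrix((size, size), geom)
        p = np.full((4, size), 1e6)
        params = n.ReconParams(n_outer=50, k_inner=1, step_a=1e9, gamma=1e-6)
        with pytest.raises(RuntimeError):
            n.art_tv_reconstruct(A, p, params)


class TestParamValidation:
    def test_defaults_match_study_settings(self):
        p = n.ReconParams()
        assert (p.lambda_, p.gamma, p.mu, p.step_a, p.k_inner) == (
            1000.0, 30.0, 30.0, 0.2, 10)

    @pytest.mark.parametrize("kwargs", [
        dict(lambda_=0.0), dict(step_a=-1.0), dict(k_inner=0),
        dict(threshold_convention="bogus"),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            n.ReconParams(**kwargs)
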