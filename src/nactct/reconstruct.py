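"""Iterative reconstruction algorithms for sparse-view parallel-beam CT.

Three solvers share one skeleton:

* :func:`art_reconstruct` — classic ART: row-sequential Kaczmarz sweeps over
  the projection data followed by a positivity clamp.
* :func:`art_tv_reconstruct` — ART data sweeps alternated with a
  Split-Bregman inner loop carrying an (anisotropic) TV penalty.
* :func:`spbr_nact_reconstruct` — the full method: the inner loop penalizes
  both the image gradient and its non-aliasing contourlet coefficients,
  min ||f||_TV + ||Phi f||_1  s.t.  ||A f - p||_2^2 < sigma^2,
  solved by Split-Bregman splitting with normalized steepest-descent steps.

The two-loop structure: each outer iteration n runs one ART sweep plus
positivity, records the step scale d(n) = ||f_before - f_after||_2, then runs
K inner Split-Bregman iterations.  Each inner iteration k sweeps the views m,
taking a descent step of length a * d(n) along the normalized gradient of the
quadratic subproblem, clamps negatives, and finishes with soft-thresholding
updates of the auxiliary variables (d_x, d_y, d_phi) and Bregman updates of
(b_x, b_y, b_phi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry_sim import SystemMatrix
from .nact import NACT, NACTCoefficients
from .regularization import (grad_x, grad_y, grad_x_adjoint, grad_y_adjoint,
                             shrink)

__all__ = ["ReconParams", "SplitBregmanState", "art_sweep", "positivity",
           "art_reconstruct", "spbr_gradient", "spbr_nact_reconstruct",
           "art_tv_reconstruct"]


@dataclass
class ReconParams:
    """Solver parameters.

    lambda_ weights the data-fidelity term, gamma the TV penalty and mu the
    contourlet penalty; step_a scales the normalized descent step; k_inner
    is the number of Split-Bregman iterations per outer (ART) iteration.
    ``sigma`` is the data-consistency stopping tolerance: iteration halts
    once ``||A f - p||_2^2 < sigma**2`` (``None`` disables the test and all
    ``n_outer`` iterations run).

    ``threshold_convention`` selects the shrinkage thresholds: the default
    ("as_printed") uses 1/lambda for the gradient channels and 1/mu for the
    contourlet channel; "weight_consistent" uses 1/(2 gamma)
    and 1/(2 mu), the thresholds implied by the quadratic weights.
    ``cache_regularization`` evaluates the regularization part of the
    gradient once per inner iteration instead of once per view.
    """

    lambda_: float = 1000.0
    gamma: float = 30.0
    mu: float = 30.0
    step_a: float = 0.2
    k_inner: int = 10
    n_outer: int = 50
    sigma: float | None = None
    threshold_convention: str = "as_printed"
    cache_regularization: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.gamma < 0 or self.mu < 0 or self.step_a <= 0:
            raise ValueError("gamma, mu must be >= 0 and step_a > 0")
        if self.k_inner < 1 or self.n_outer < 1:
            raise ValueError("k_inner and n_outer must be >= 1")
        if self.threshold_convention not in ("as_printed", "weight_consistent"):
            raise ValueError("unknown threshold_convention")

    def thresholds(self) -> tuple[float, float]:
        """(gradient-channel, contourlet-channel) shrinkage thresholds."""
        if self.threshold_convention == "as_printed":
            return 1.0 / self.lambda_, (1.0 / self.mu if self.mu > 0 else 0.0)
        return (1.0 / (2.0 * self.gamma) if self.gamma > 0 else 0.0,
                1.0 / (2.0 * self.mu) if self.mu > 0 else 0.0)


@dataclass
class SplitBregmanState:
    """Auxiliary and Bregman variables of the inner loop."""

    dx: np.ndarray
    dy: np.ndarray
    bx: np.ndarray
    by: np.ndarray
    dphi: NACTCoefficients | None = None
    bphi: NACTCoefficients | None = None
    d_n: float = 0.0


def positivity(f: np.ndarray) -> np.ndarray:
    """Clamp negative pixels to zero."""
    return np.maximum(f, 0.0)


def _row_cache(A: SystemMatrix):
    """Per-row (CSR arrays, inverse squared norms) for Kaczmarz sweeps."""
    cache = getattr(A, "_kaczmarz_cache", None)
    if cache is None:
        M = A.matrix.tocsr()
        norms2 = np.asarray(M.multiply(M).sum(axis=1)).ravel()
        inv = np.zeros_like(norms2)
        nz = norms2 > 0
        inv[nz] = 1.0 / norms2[nz]
        cache = (M.indptr, M.indices, M.data, inv)
        A._kaczmarz_cache = cache
    return cache


def art_sweep(f: np.ndarray, A: SystemMatrix, p: np.ndarray) -> np.ndarray:
    """One full Kaczmarz sweep: rows visited sequentially in view order.

    Each row update projects the current image onto that ray's hyperplane,
    ``f <- f + a_m (p_m - a_m . f) / (a_m . a_m)``; zero rows are skipped.
    """
    if A.matrix.nnz == 0:
        raise ValueError("system matrix is identically zero")
    if p.shape != (A.geometry.n_views, A.geometry.n_detectors):
        raise ValueError("sinogram shape does not match the geometry")
    indptr, indices, data, inv = _row_cache(A)
    x = f.ravel().copy()
    pv = p.ravel()
    for r in range(len(inv)):
        if inv[r] == 0.0:
            continue
        lo, hi = indptr[r], indptr[r + 1]
        idx = indices[lo:hi]
        row = data[lo:hi]
        resid = pv[r] - row @ x[idx]
        x[idx] += row * (resid * inv[r])
    return x.reshape(f.shape)


def art_reconstruct(
    A: SystemMatrix,
    p: np.ndarray,
    params: ReconParams | None = None,
    callback=None,
) -> np.ndarray:
    """ART: ``n_outer`` repetitions of (Kaczmarz sweep, positivity) from zero."""
    params = params or ReconParams()
    f = np.zeros(A.image_shape)
    pv = p.ravel()
    for n in range(params.n_outer):
        f = positivity(art_sweep(f, A, p))
        if callback is not None:
            callback(n + 1, f)
        if params.sigma is not None:
            res2 = float(np.sum((A.matrix @ f.ravel() - pv) ** 2))
            if res2 < params.sigma**2:
                break
    return f


def _reg_gradient(
    f: np.ndarray,
    state: SplitBregmanState,
    params: ReconParams,
    transform: NACT | None,
) -> np.ndarray:
    """Regularization part of the quadratic-subproblem gradient at ``f``."""
    g = np.zeros_like(f)
    if params.gamma > 0:
        g -= 2.0 * params.gamma * grad_x_adjoint(state.dx - grad_x(f) - state.bx)
        g -= 2.0 * params.gamma * grad_y_adjoint(state.dy - grad_y(f) - state.by)
    if params.mu > 0 and transform is not None:
        resid = state.dphi - transform.forward(f) - state.bphi
        g -= 2.0 * params.mu * transform.adjoint(resid)
    return g


def spbr_gradient(
    f: np.ndarray,
    A: SystemMatrix,
    p: np.ndarray,
    state: SplitBregmanState,
    params: ReconParams,
    m: int,
    transform: NACT | None = None,
    reg_cache: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized descent direction of the inner quadratic subproblem at view m.

    ``g = 2 lambda A_m^T (A_m f - p_m) - 2 gamma grad_x^T(d_x - grad_x f - b_x)
    - 2 gamma grad_y^T(d_y - grad_y f - b_y) - 2 mu Phi^T(d_phi - Phi f -
    b_phi)``, returned as ``g / ||g||_2`` (zero if ``g`` vanishes).
    """
    Am = A.view_block(m)
    pm = p[m]
    r = Am @ f.ravel() - pm
    g = (2.0 * params.lambda_) * (Am.T @ r).reshape(f.shape)
    g += reg_cache if reg_cache is not None else _reg_gradient(f, state, params, transform)
    norm = float(np.linalg.norm(g))
    if norm == 0.0:
        return np.zeros_like(g)
    return g / norm


def _two_loop_reconstruct(
    A: SystemMatrix,
    p: np.ndarray,
    params: ReconParams,
    transform: NACT | None,
    callback=None,
) -> np.ndarray:
    """Shared engine behind ART-TV and the full contourlet-regularized solver."""
    if A.matrix.nnz == 0:
        raise ValueError("system matrix is identically zero")
    use_phi = params.mu > 0 and transform is not None
    f = np.zeros(A.image_shape)
    pv = p.ravel()
    n_views = A.geometry.n_views
    res0 = float(np.linalg.norm(pv))  # data residual at the zero start
    t_xy, t_phi = params.thresholds()

    for n in range(params.n_outer):
        f_start = f.copy()
        f = positivity(art_sweep(f, A, p))
        d_n = float(np.linalg.norm(f_start - f))

        if d_n > 0.0:
            state = SplitBregmanState(
                dx=grad_x(f), dy=grad_y(f),
                bx=np.zeros_like(f), by=np.zeros_like(f),
                dphi=transform.forward(f) if use_phi else None,
                bphi=transform.forward(f).zeros_like() if use_phi else None,
                d_n=d_n,
            )
            step = params.step_a * d_n
            for _k in range(params.k_inner):
                reg = (_reg_gradient(f, state, params, transform if use_phi else None)
                       if params.cache_regularization else None)
                for m in range(n_views):
                    ghat = spbr_gradient(f, A, p, state, params, m,
                                         transform if use_phi else None,
                                         reg_cache=reg)
                    f = f - step * ghat
                f = positivity(f)
                gxf, gyf = grad_x(f), grad_y(f)
                state.dx = shrink(gxf + state.bx, t_xy)
                state.dy = shrink(gyf + state.by, t_xy)
                state.bx = state.bx + (gxf - state.dx)
                state.by = state.by + (gyf - state.dy)
                if use_phi:
                    phif = transform.forward(f)
                    state.dphi = shrink(phif + state.bphi, t_phi)
                    state.bphi = state.bphi + (phif - state.dphi)

        res = float(np.linalg.norm(A.matrix @ f.ravel() - pv))
        if res > 10.0 * res0:
            raise RuntimeError(
                f"divergence detected at outer iteration {n + 1}: data residual "
                f"{res:.3e} exceeds 10x its starting value {res0:.3e}"
            )
        if callback is not None:
            callback(n + 1, f)
        if params.sigma is not None and res**2 < params.sigma**2:
            break
    return f


def spbr_nact_reconstruct(
    A: SystemMatrix,
    p: np.ndarray,
    params: ReconParams | None = None,
    transform: NACT | None = None,
    callback=None,
) -> np.ndarray:
    """Split-Bregman reconstruction with joint TV + contourlet regularization."""
    params = params or ReconParams()
    if params.mu > 0 and transform is None:
        transform = NACT()
    return _two_loop_reconstruct(A, p, params, transform, callback)


def art_tv_reconstruct(
    A: SystemMatrix,
    p: np.ndarray,
    params: ReconParams | None = None,
    callback=None,
) -> np.ndarray:
    """TV-only baseline: the two-loop solver with the contourlet channel off."""
    params = params or ReconParams()
    if params.mu != 0:
        params = ReconParams(
            lambda_=params.lambda_, gamma=params.gamma, mu=0.0,
            step_a=params.step_a, k_inner=params.k_inner,
            n_outer=params.n_outer, sigma=params.sigma,
            threshold_convention=params.threshold_convention,
            cache_regularization=params.cache_regularization,
        )
    return _two_loop_reconstruct(A, p, params, None, callback)
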