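"""Total-variation operators and the soft-thresholding (shrinkage) operator.

Gradients are backward finite differences, ``(grad_x f)[s,t] = f[s,t] -
f[s,t-1]`` along columns and ``(grad_y f)[s,t] = f[s,t] - f[s-1,t]`` along
rows.  The boundary convention is replicate: differences that would reference
a sample outside the grid are zero, so the first row of grad_y and the first
column of grad_x vanish and the TV of a constant image is exactly zero.
"""

from __future__ import annotations

import numpy as np

__all__ = ["grad_x", "grad_y", "grad", "grad_x_adjoint", "grad_y_adjoint",
           "grad_adjoint", "tv", "shrink"]


def _check_image(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2 or f.shape[1] < 2:
        raise ValueError("expected a 2-D image of size at least 2x2")
    return f


def grad_x(f: np.ndarray) -> np.ndarray:
    """Backward difference along columns; first column is zero."""
    f = _check_image(f)
    g = np.zeros_like(f)
    g[:, 1:] = f[:, 1:] - f[:, :-1]
    return g


def grad_y(f: np.ndarray) -> np.ndarray:
    """Backward difference along rows; first row is zero."""
    f = _check_image(f)
    g = np.zeros_like(f)
    g[1:, :] = f[1:, :] - f[:-1, :]
    return g


def grad(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Both gradient channels ``(grad_x f, grad_y f)``."""
    return grad_x(f), grad_y(f)


def grad_x_adjoint(g: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`grad_x` (negative divergence along columns)."""
    g = np.asarray(g, dtype=float)
    out = np.zeros_like(g)
    out[:, :-1] = -g[:, 1:]
    out[:, 1:] += g[:, 1:]
    return out


def grad_y_adjoint(g: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`grad_y` (negative divergence along rows)."""
    g = np.asarray(g, dtype=float)
    out = np.zeros_like(g)
    out[:-1, :] = -g[1:, :]
    out[1:, :] += g[1:, :]
    return out


def grad_adjoint(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    if gx.shape != gy.shape:
        raise ValueError("gradient channels must share a shape")
    return grad_x_adjoint(gx) + grad_y_adjoint(gy)


def tv(f: np.ndarray) -> float:
    """Isotropic total variation: sum of per-pixel gradient magnitudes."""
    gx, gy = grad(f)
    return float(np.sum(np.sqrt(gx**2 + gy**2)))


def shrink(x, t):
    """Soft thresholding ``sign(x) * max(|x| - t, 0)``.

    The proximal operator of ``t * |.|``; applied elementwise to scalars,
    arrays, or transform-coefficient objects exposing ``.map``.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("threshold must be nonnegative")
    if hasattr(x, "map"):  # e.g. NACTCoefficients
        return x.map(lambda b: shrink(b, t))
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
    return float(out) if out.ndim == 0 else out
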