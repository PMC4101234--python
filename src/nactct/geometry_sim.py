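"""Phantom generation, projection geometry and pencil-beam sinogram simulation.

The scanner is an idealized parallel ("pencil") beam: one straight ray per
detector sample, detectors spaced one pixel apart, rays rotated
counterclockwise about the image center.  The system matrix holds exact
ray/pixel intersection lengths (Siddon-style ray tracing), so forward
projection of an image is a genuine discrete line integral in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SHEPP_LOGAN_ELLIPSES",
    "ProjectionGeometry",
    "make_phantom",
    "make_angles",
    "build_system_matrix",
    "project",
    "add_noise",
]

# Modified (contrast-enhanced) Shepp-Logan head phantom.
# Columns: additive intensity, semi-axis a (x), semi-axis b (y),
# center x0, center y0, rotation angle phi in degrees (CCW).
# Coordinates live in the unit square [-1, 1] x [-1, 1].
SHEPP_LOGAN_ELLIPSES = np.array(
    [
        [1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0],
        [-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0],
        [-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0],
        [-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0],
        [0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0],
        [0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0],
        [0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0],
        [0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0],
        [0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0],
        [0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0],
    ]
)


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam acquisition geometry.

    Parameters
    ----------
    angles
        View angles in degrees, counterclockwise. One sinogram row per angle.
    n_detectors
        Number of detector bins per view.
    detector_spacing
        Distance between adjacent detector bins, in pixel units.
    """

    angles: np.ndarray
    n_detectors: int
    detector_spacing: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        if self.angles.ndim != 1 or self.angles.size == 0:
            raise ValueError("geometry requires a non-empty 1-D list of angles")
        if self.n_detectors <= 0:
            raise ValueError("n_detectors must be positive")

    @property
    def n_views(self) -> int:
        return int(self.angles.size)


@dataclass
class SystemMatrix:
    """Sparse ray/pixel intersection operator with per-view row blocks.

    ``matrix`` has shape (n_views * n_detectors, M * N); row (m, d) holds the
    intersection lengths of the ray at view m, detector d with every pixel.
    """

    matrix: sp.csr_matrix
    geometry: ProjectionGeometry
    image_shape: tuple[int, int]
    _view_blocks: list[sp.csr_matrix] = field(default_factory=list, repr=False)

    def view_block(self, m: int) -> sp.csr_matrix:
        """Rows of view m (all detectors at angle ``geometry.angles[m]``)."""
        if not self._view_blocks:
            nd = self.geometry.n_detectors
            self._view_blocks = [
                self.matrix[m * nd : (m + 1) * nd] for m in range(self.geometry.n_views)
            ]
        return self._view_blocks[m]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def make_phantom(size: int) -> np.ndarray:
    """Rasterize the modified Shepp-Logan head phantom at ``size`` x ``size``.

    Pixel-center membership: a pixel receives the summed intensity of every
    ellipse whose interior contains its center. Intensities lie in [0, 1].
    """
    if size < 16:
        raise ValueError("phantom size must be at least 16")
    # Pixel centers on [-1, 1]; row 0 is the top of the image (y = +1 side).
    c = (np.arange(size) + 0.5) / size * 2.0 - 1.0
    x = c[np.newaxis, :]
    y = -c[:, np.newaxis]
    f = np.zeros((size, size))
    for amp, a, b, x0, y0, phi in SHEPP_LOGAN_ELLIPSES:
        t = np.deg2rad(phi)
        xr = (x - x0) * np.cos(t) + (y - y0) * np.sin(t)
        yr = -(x - x0) * np.sin(t) + (y - y0) * np.cos(t)
        f += amp * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return np.clip(f, 0.0, 1.0)


def make_angles(n_views: int) -> np.ndarray:
    """Interleaved two-arc view schedule.

    First half: theta_i = 1 + 360 (i - 1) / N for i = 1 .. N/2.
    Second half: theta_i = 182 + 360 (i - N/2) / N for i = N/2 + 1 .. N.
    The second arc starts one angular increment past 182 deg so that exactly
    ``n_views`` distinct views are produced. Angles are in degrees and may
    exceed 360; they are used modulo 360 by the ray tracer.
    """
    if n_views < 2 or n_views % 2 != 0:
        raise ValueError("n_views must be an even number >= 2")
    i = np.arange(1, n_views // 2 + 1)
    first = 1.0 + 360.0 * (i - 1) / n_views
    second = 182.0 + 360.0 * i / n_views
    return np.concatenate([first, second])


def _ray_pixel_intersections(
    n: int, theta_deg: float, t_offset: float
) -> tuple[np.ndarray, np.ndarray]:
    """Siddon-style exact intersection lengths of one ray with an n x n grid.

    The grid occupies [-n/2, n/2]^2 in pixel units. The ray has direction
    (cos theta, sin theta) and passes through the point t_offset * u where
    u = (-sin theta, cos theta) is the detector axis.

    Returns (flat pixel indices, intersection lengths).
    """
    t = np.deg2rad(theta_deg)
    dx, dy = np.cos(t), np.sin(t)
    px, py = -t_offset * np.sin(t), t_offset * np.cos(t)
    half = n / 2.0

    # Parametric entry/exit of the bounding box (slab intersection).
    lo, hi = -np.inf, np.inf
    for p0, d in ((px, dx), (py, dy)):
        if abs(d) > 1e-12:
            s1, s2 = (-half - p0) / d, (half - p0) / d
            lo = max(lo, min(s1, s2))
            hi = min(hi, max(s1, s2))
        elif not (-half <= p0 <= half):
            return np.empty(0, dtype=np.int64), np.empty(0)
    if hi <= lo:
        return np.empty(0, dtype=np.int64), np.empty(0)

    # All crossings of pixel edges between entry and exit.
    edges = np.arange(-half, half + 1.0)
    crossings = [np.array([lo, hi])]
    if abs(dx) > 1e-12:
        sx = (edges - px) / dx
        crossings.append(sx[(sx > lo) & (sx < hi)])
    if abs(dy) > 1e-12:
        sy = (edges - py) / dy
        crossings.append(sy[(sy > lo) & (sy < hi)])
    s = np.unique(np.concatenate(crossings))
    if s.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)
    lengths = np.diff(s)
    mid = (s[:-1] + s[1:]) / 2.0
    mx = px + mid * dx
    my = py + mid * dy
    col = np.floor(mx + half).astype(np.int64)
    row = np.floor(half - my).astype(np.int64)
    keep = (col >= 0) & (col < n) & (row >= 0) & (row < n) & (lengths > 1e-12)
    return (row[keep] * n + col[keep]), lengths[keep]


def build_system_matrix(
    image_shape: tuple[int, int], geometry: ProjectionGeometry
) -> SystemMatrix:
    """Build the sparse parallel-beam system matrix for ``image_shape``.

    Row (m, d) traces the ray at angle ``angles[m]`` and detector offset
    ``(d - (n_detectors - 1)/2) * detector_spacing`` through the pixel grid.
    """
    m_rows, n_cols = image_shape
    if m_rows != n_cols:
        raise ValueError("only square images are supported")
    n = n_cols
    nd = geometry.n_detectors
    offsets = (np.arange(nd) - (nd - 1) / 2.0) * geometry.detector_spacing

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for m, theta in enumerate(geometry.angles):
        base = m * nd
        for d, t_off in enumerate(offsets):
            idx, lengths = _ray_pixel_intersections(n, float(theta), float(t_off))
            if idx.size:
                rows.append(np.full(idx.size, base + d, dtype=np.int64))
                cols.append(idx)
                vals.append(lengths)
    if not rows:
        raise ValueError("no ray intersects the image: empty system matrix")
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geometry.n_views * nd, n * n),
    )
    return SystemMatrix(matrix=A, geometry=geometry, image_shape=image_shape)


def project(A: SystemMatrix, f: np.ndarray) -> np.ndarray:
    """Forward projection p = A f, reshaped to (n_views, n_detectors)."""
    if f.shape != A.image_shape:
        raise ValueError(f"image shape {f.shape} does not match {A.image_shape}")
    p = A.matrix @ f.ravel()
    return p.reshape(A.geometry.n_views, A.geometry.n_detectors)


def add_noise(
    p: np.ndarray, snr_db: float, seed: int = 0, reference: str = "signal"
) -> np.ndarray:
    """Add zero-mean white Gaussian noise at a prescribed level in dB.

    With ``reference="signal"`` the noise variance is set against the
    measured signal power (mean square of the sinogram, DC included) so that
    ``10 log10(mean(p^2) / var) = snr_db``.  With ``reference="unit"`` the
    variance is the absolute power ``10**(-snr_db / 10)`` — the convention of
    dB relative to unit power, which for CT-scale sinograms (line integrals
    of tens of pixel units) yields a far milder perturbation than a measured
    SNR of the same nominal figure.  ``snr_db=inf`` disables noise.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty sinogram")
    if np.isinf(snr_db):
        return p.copy()
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite or +inf")
    if reference == "signal":
        noise_power = float(np.mean(p**2)) / 10.0 ** (snr_db / 10.0)
    elif reference == "unit":
        noise_power = 10.0 ** (-snr_db / 10.0)
    else:
        raise ValueError("reference must be 'signal' or 'unit'")
    rng = np.random.default_rng(seed)
    return p + rng.normal(0.0, np.sqrt(noise_power), size=p.shape)
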