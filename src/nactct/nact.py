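"""Non-aliasing contourlet transform (NACT).

A multiscale, multidirectional image decomposition built from two stages:

* **NPFB** — non-aliasing pyramidal filter banks realized as multiplicative
  frequency windows on the FFT grid.  The first stage splits the spectrum
  with a low/high pair (L0, D0) satisfying ``D0^2 + L0^2 = 1`` and is not
  decimated; every subsequent stage uses a pair (L1, D1) with
  ``D1^2 + L1^2/4 = 1`` (L1 has pass-band amplitude 2) and decimates the
  low-pass branch by 2 per axis.  The low-pass stop-band edges sit strictly
  inside the alias-free region, so decimation is a pure spectrum crop and
  introduces no aliasing.

* **DFB** — directional filter banks realized as smooth angular wedge
  windows whose squared magnitudes form a partition of unity over
  orientation, splitting each detail band into 2^n directional subbands
  (undecimated).

Both stages preserve energy, so the whole transform is a Parseval tight
frame: the adjoint equals the inverse and round-trip reconstruction is exact
to machine precision.  Window transitions use the classic Meyer polynomial
``nu(t) = t^4 (35 - 84 t + 70 t^2 - 20 t^3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2, ifft2

__all__ = [
    "NPFBSpec",
    "DFBSpec",
    "NACTCoefficients",
    "NACT",
    "design_npfb",
    "nact_forward",
    "nact_inverse",
    "nact_adjoint",
]


def _meyer_nu(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t**4 * (35.0 - 84.0 * t + 70.0 * t**2 - 20.0 * t**3)


def _lowpass_profile(r: np.ndarray, wp: float, ws: float) -> np.ndarray:
    """Unit-amplitude low-pass radial profile: 1 below wp, 0 above ws."""
    t = (r - wp) / (ws - wp)
    return np.cos(0.5 * np.pi * _meyer_nu(t)) * (r < ws) + 0.0 * (r >= ws)


def _freq_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    wy = 2.0 * np.pi * np.fft.fftfreq(shape[0])[:, np.newaxis]
    wx = 2.0 * np.pi * np.fft.fftfreq(shape[1])[np.newaxis, :]
    return wy, wx


@dataclass(frozen=True)
class NPFBSpec:
    """Pass/stop-band edges (radians) of the pyramid's low-pass windows.

    ``(wp0, ws0)`` belong to the undecimated first-stage low-pass L0,
    ``(wp1, ws1)`` to the decimated-stage low-pass L1.  The anti-aliasing
    constraints tie the edges to the directional mixing width ``a``:
    ``(wp0+ws0)/2 = pi/2``, ``(wp1+ws1)/2 = pi/4``, ``ws0 <= pi - a``,
    ``ws1 <= (pi - a)/2`` and ``ws1 < pi/2``.
    """

    wp0: float
    ws0: float
    wp1: float
    ws1: float
    a: float = 0.2 * np.pi

    def __post_init__(self) -> None:
        if not (0 < self.wp0 < self.ws0 and 0 < self.wp1 < self.ws1):
            raise ValueError("band edges must satisfy 0 < wp < ws")
        if abs((self.wp0 + self.ws0) / 2 - np.pi / 2) > 1e-9:
            raise ValueError("(wp0+ws0)/2 must equal pi/2")
        if abs((self.wp1 + self.ws1) / 2 - np.pi / 4) > 1e-9:
            raise ValueError("(wp1+ws1)/2 must equal pi/4")
        if self.ws1 >= np.pi / 2:
            raise ValueError("ws1 must be below pi/2 (alias-free decimation)")
        if self.ws0 > np.pi - self.a + 1e-9 or self.ws1 > (np.pi - self.a) / 2 + 1e-9:
            raise ValueError("stop-band edges violate the anti-aliasing width a")

    def windows(self, shape: tuple[int, int], stage: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (L, D) on the unshifted FFT grid of ``shape``.

        ``stage=0``: (L0, D0) with D0^2 + L0^2 = 1.
        ``stage=1``: (L1, D1) with D1^2 + L1^2/4 = 1 (L1 peaks at 2).
        """
        wy, wx = _freq_grid(shape)
        r = np.maximum(np.abs(wy), np.abs(wx))
        if stage == 0:
            low = _lowpass_profile(r, self.wp0, self.ws0)
            return low, np.sqrt(np.clip(1.0 - low**2, 0.0, None))
        low = _lowpass_profile(r, self.wp1, self.ws1)
        return 2.0 * low, np.sqrt(np.clip(1.0 - low**2, 0.0, None))


def design_npfb(
    grid_shape: tuple[int, int] = (64, 64),
    a: float = 0.2 * np.pi,
    transition_width: tuple[float, float] | None = None,
) -> NPFBSpec:
    """Design NPFB band edges for a given directional mixing width ``a``.

    The transition half-widths default to the widest symmetric transitions
    allowed by the anti-aliasing constraints, capped at (0.2 pi, 0.1 pi).
    ``grid_shape`` only bounds how narrow a transition the grid can resolve.
    """
    if min(grid_shape) < 8:
        raise ValueError("grid must be at least 8x8")
    if not 0 < a < np.pi / 2:
        raise ValueError("a must lie in (0, pi/2)")
    if transition_width is None:
        w0 = min(0.2 * np.pi, np.pi / 2 - a)
        w1 = min(0.1 * np.pi, (np.pi / 2 - a) / 2)
    else:
        w0, w1 = transition_width
    dw = 2.0 * np.pi / max(grid_shape)
    if w0 < dw or w1 < dw:
        raise ValueError("transition narrower than one frequency-grid step")
    return NPFBSpec(
        wp0=np.pi / 2 - w0, ws0=np.pi / 2 + w0,
        wp1=np.pi / 4 - w1, ws1=np.pi / 4 + w1, a=a,
    )


@dataclass(frozen=True)
class DFBSpec:
    """Directional wedge windows over orientation (modulo pi).

    ``transition_frac`` is the fraction of a wedge's angular half-width used
    for the smooth crossfade between neighbouring directions; squared window
    magnitudes sum to one at every frequency, keeping the bank tight.
    """

    transition_frac: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.transition_frac <= 1:
            raise ValueError("transition_frac must lie in (0, 1]")

    def windows(self, shape: tuple[int, int], n_dirs: int) -> list[np.ndarray]:
        if n_dirs < 1 or (n_dirs & (n_dirs - 1)) != 0:
            raise ValueError("n_dirs must be a power of two")
        if n_dirs == 1:
            return [np.ones(shape)]
        wy, wx = _freq_grid(shape)
        phi = np.mod(np.arctan2(np.broadcast_to(wy, (shape[0], shape[1])),
                                np.broadcast_to(wx, (shape[0], shape[1]))), np.pi)
        hw = np.pi / (2 * n_dirs)
        tw = self.transition_frac * hw
        out = []
        for j in range(n_dirs):
            center = j * np.pi / n_dirs
            delta = np.abs(np.mod(phi - center + np.pi / 2, np.pi) - np.pi / 2)
            t = (delta - (hw - tw)) / (2.0 * tw)
            w = np.cos(0.5 * np.pi * _meyer_nu(t))
            w[delta >= hw + tw] = 0.0
            w[delta <= hw - tw] = 1.0
            # Symmetrize under omega -> -omega (the Nyquist row/column maps
            # onto itself with negated partner, where the wedge angle is
            # ambiguous).  Averaging the squared windows keeps the partition
            # of unity exact and makes every subband exactly real.
            mirror = np.roll(w[::-1, ::-1], 1, axis=(0, 1))
            out.append(np.sqrt(0.5 * (w**2 + mirror**2)))
        return out


@dataclass
class NACTCoefficients:
    """Transform coefficients: coarse approximation + directional details.

    ``details[l][j]`` is the j-th directional subband at decomposition level
    l (level 0 is the finest scale).  The frame is redundant: the total
    coefficient count exceeds the pixel count.
    """

    approx: np.ndarray
    details: list[list[np.ndarray]]

    @property
    def levels(self) -> int:
        return len(self.details)

    @property
    def dirs_per_level(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.details)

    def map(self, fn) -> "NACTCoefficients":
        return NACTCoefficients(
            approx=fn(self.approx),
            details=[[fn(b) for b in lev] for lev in self.details],
        )

    def _binary(self, other: "NACTCoefficients", fn) -> "NACTCoefficients":
        return NACTCoefficients(
            approx=fn(self.approx, other.approx),
            details=[
                [fn(a, b) for a, b in zip(la, lb)]
                for la, lb in zip(self.details, other.details)
            ],
        )

    def __add__(self, other: "NACTCoefficients") -> "NACTCoefficients":
        return self._binary(other, np.add)

    def __sub__(self, other: "NACTCoefficients") -> "NACTCoefficients":
        return self._binary(other, np.subtract)

    def __mul__(self, c: float) -> "NACTCoefficients":
        return self.map(lambda x: x * c)

    __rmul__ = __mul__

    def norm(self) -> float:
        total = float(np.sum(self.approx**2))
        for lev in self.details:
            for b in lev:
                total += float(np.sum(b**2))
        return np.sqrt(total)

    def zeros_like(self) -> "NACTCoefficients":
        return self.map(np.zeros_like)

    def size(self) -> int:
        return self.approx.size + sum(b.size for lev in self.details for b in lev)


class NACT:
    """Forward / inverse / adjoint non-aliasing contourlet transform.

    Parameters
    ----------
    levels
        Number of pyramid levels (>= 1).  Level 1 is undecimated; each
        further level halves the low-pass grid, so image dimensions must be
        divisible by ``2**(levels-1)``.
    dirs_per_level
        Directional subbands per level, finest first; each a power of two.
    npfb, dfb
        Filter-bank specifications; sensible defaults are designed from the
        mixing width ``a``.
    """

    def __init__(
        self,
        levels: int = 3,
        dirs_per_level: tuple[int, ...] = (4, 8, 8),
        npfb: NPFBSpec | None = None,
        dfb: DFBSpec | None = None,
        a: float = 0.2 * np.pi,
    ):
        if levels < 1:
            raise ValueError("levels must be >= 1")
        if len(dirs_per_level) != levels:
            raise ValueError("dirs_per_level must have one entry per level")
        self.levels = levels
        self.dirs_per_level = tuple(int(d) for d in dirs_per_level)
        self.npfb = npfb if npfb is not None else design_npfb(a=a)
        self.dfb = dfb if dfb is not None else DFBSpec()
        self._win_cache: dict = {}

    # -- window plumbing ---------------------------------------------------

    def _check_shape(self, shape: tuple[int, int]) -> None:
        div = 2 ** (self.levels - 1)
        if shape[0] % div or shape[1] % div:
            raise ValueError(
                f"image dimensions {shape} must be divisible by {div} "
                f"for a {self.levels}-level decomposition"
            )

    def _stage_windows(self, shape: tuple[int, int], level: int):
        """(L, per-direction D*W windows) for the given level at ``shape``."""
        key = (shape, level)
        if key not in self._win_cache:
            stage = 0 if level == 0 else 1
            low, high = self.npfb.windows(shape, stage)
            dirs = self.dfb.windows(shape, self.dirs_per_level[level])
            self._win_cache[key] = (low, [high * w for w in dirs])
        return self._win_cache[key]

    @staticmethod
    def _crop(X: np.ndarray) -> np.ndarray:
        """Central spectrum crop to half size per axis (alias-free decimation)."""
        Xs = np.fft.fftshift(X)
        slices = []
        for n in X.shape:
            m = n // 2
            start = n // 2 - m // 2
            slices.append(slice(start, start + m))
        return np.fft.ifftshift(Xs[slices[0], slices[1]])

    @staticmethod
    def _pad(X: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Adjoint of :meth:`_crop`: embed the spectrum centrally in ``shape``."""
        Xs = np.fft.fftshift(X)
        out = np.zeros(shape, dtype=X.dtype)
        sl = []
        for n, m in zip(shape, X.shape):
            start = n // 2 - m // 2
            sl.append(slice(start, start + m))
        out[sl[0], sl[1]] = Xs
        return np.fft.ifftshift(out)

    # -- transform ---------------------------------------------------------

    def forward(self, f: np.ndarray) -> NACTCoefficients:
        """Decompose ``f`` into directional detail subbands + approximation."""
        f = np.asarray(f, dtype=float)
        if f.ndim != 2:
            raise ValueError("input must be a 2-D image")
        self._check_shape(f.shape)
        X = fft2(f)
        details: list[list[np.ndarray]] = []
        for level in range(self.levels):
            low, dir_windows = self._stage_windows(X.shape, level)
            details.append([ifft2(w * X).real for w in dir_windows])
            if level == 0:
                X = low * X
            else:
                X = 0.25 * self._crop(low * X)
        return NACTCoefficients(approx=ifft2(X).real, details=details)

    def adjoint(self, c: NACTCoefficients) -> np.ndarray:
        """Adjoint of :meth:`forward`; equals the inverse (Parseval frame)."""
        if c.levels != self.levels or c.dirs_per_level != self.dirs_per_level:
            raise ValueError("coefficient layout does not match this transform")
        X = fft2(np.asarray(c.approx, dtype=float))
        for level in reversed(range(self.levels)):
            if level >= 1:
                shape = (X.shape[0] * 2, X.shape[1] * 2)
                low, dir_windows = self._stage_windows(shape, level)
                X = low * self._pad(X, shape)
            else:
                low, dir_windows = self._stage_windows(X.shape, level)
                X = low * X
            for w, band in zip(dir_windows, c.details[level]):
                if band.shape != X.shape:
                    raise ValueError("detail subband shape inconsistent")
                X = X + w * fft2(np.asarray(band, dtype=float))
        return ifft2(X).real

    # Tight (Parseval) frame: synthesis coincides with the adjoint.
    inverse = adjoint


# -- functional wrappers ---------------------------------------------------

def _transform(npfb, dfb, levels, dirs_per_level) -> NACT:
    return NACT(levels=levels, dirs_per_level=tuple(dirs_per_level),
                npfb=npfb, dfb=dfb)


def nact_forward(
    f: np.ndarray,
    npfb: NPFBSpec | None = None,
    dfb: DFBSpec | None = None,
    levels: int = 3,
    dirs_per_level: tuple[int, ...] = (4, 8, 8),
) -> NACTCoefficients:
    return _transform(npfb, dfb, levels, dirs_per_level).forward(f)


def nact_inverse(
    c: NACTCoefficients,
    npfb: NPFBSpec | None = None,
    dfb: DFBSpec | None = None,
) -> np.ndarray:
    return _transform(npfb, dfb, c.levels, c.dirs_per_level).inverse(c)


def nact_adjoint(
    c: NACTCoefficients,
    npfb: NPFBSpec | None = None,
    dfb: DFBSpec | None = None,
) -> np.ndarray:
    return _transform(npfb, dfb, c.levels, c.dirs_per_level).adjoint(c)
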