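"""Image-quality metrics: root-mean-square error and the universal quality
index (UQI) of Wang and Bovik, computed globally over the whole image."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["rmse", "uqi", "MetricReport", "evaluate"]


def _pair(f: np.ndarray, fr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=float)
    fr = np.asarray(fr, dtype=float)
    if f.shape != fr.shape:
        raise ValueError(f"image shapes differ: {f.shape} vs {fr.shape}")
    return f, fr


def rmse(f: np.ndarray, fr: np.ndarray) -> float:
    """Root-mean-square error, mean taken over all pixels."""
    f, fr = _pair(f, fr)
    return float(np.sqrt(np.mean((f - fr) ** 2)))


def uqi(f: np.ndarray, fr: np.ndarray) -> float:
    """Universal quality index in [-1, 1]; 1 iff the images coincide.

    Combines correlation, luminance and contrast distortion:
    ``4 cov(f, fr) mean(f) mean(fr) / ((var f + var fr)(mean(f)^2 + mean(fr)^2))``
    with sample (n-1) normalization for variances and covariance, evaluated
    in a single global window.
    """
    f, fr = _pair(f, fr)
    n = f.size
    mf, mr = float(np.mean(f)), float(np.mean(fr))
    df, dr = f - mf, fr - mr
    vf = float(np.sum(df**2)) / (n - 1)
    vr = float(np.sum(dr**2)) / (n - 1)
    cov = float(np.sum(df * dr)) / (n - 1)
    denom = (vf + vr) * (mf**2 + mr**2)
    if denom == 0.0:
        # Both images constant: identical constants are a perfect match.
        warnings.warn("UQI denominator is zero (both images constant)")
        return 1.0 if mf == mr else 0.0
    return float(4.0 * cov * mf * mr / denom)


@dataclass
class MetricReport:
    rmse: float
    uqi: float


def evaluate(f: np.ndarray, fr: np.ndarray) -> MetricReport:
    """Convenience wrapper returning both metrics for a reconstruction."""
    return MetricReport(rmse=rmse(f, fr), uqi=uqi(f, fr))
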