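"""Closed-form profile of a uniform sphere blurred by an isotropic Gaussian.

For a unit-contrast sphere of radius R convolved with a Gaussian of width σ,
the blurred intensity at distance d from the center is

    A(d) = 1/2 [erf((R+d)/(σ√2)) + erf((R−d)/(σ√2))]
           − σ/(d√(2π)) [exp(−(R−d)²/2σ²) − exp(−(R+d)²/2σ²)]

with the d→0 limit A(0) = erf(R/(σ√2)) − √(2/π)(R/σ)exp(−R²/2σ²).

Because A is radially non-increasing, the iso-contour at r = R encloses
exactly the true sphere volume, so 100·A(R)/A(0) is the volume-matching
relative threshold in the continuous (noise-free, infinitesimal-pixel)
limit.  It depends only on D/FWHM.  These closed forms are the independent
oracle for the numeric simulator and threshold solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .imaging import fwhm_to_sigma

__all__ = ["ContinuousSphereModel", "profile", "continuous_threshold"]


@dataclass(frozen=True)
class ContinuousSphereModel:
    """Sphere radius and PSF width for the continuous blur model.

    ``contrast`` scales the profile; the default 1 gives the normalized
    (uptake − background = 1) field.
    """

    radius_mm: float
    sigma_mm: float
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.sigma_mm <= 0:
            raise ValueError("radius_mm and sigma_mm must be positive")


def profile(d: float | np.ndarray, model: ContinuousSphereModel) -> np.ndarray | float:
    """Blurred sphere intensity at distance ``d`` from the center.

    Vectorized in ``d`` (must be ≥ 0).  Returns ``contrast * A(d)``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("d must be non-negative")
    R = model.radius_mm
    s = model.sigma_mm
    rt2 = math.sqrt(2.0)

    small = d < 1e-6 * s
    dd = np.where(small, 1.0, d)  # placeholder to avoid 0/0; overwritten below
    a = 0.5 * (erf((R + dd) / (s * rt2)) + erf((R - dd) / (s * rt2))) - (
        s / (dd * math.sqrt(2.0 * math.pi))
    ) * (np.exp(-((R - dd) ** 2) / (2 * s * s)) - np.exp(-((R + dd) ** 2) / (2 * s * s)))
    a0 = erf(R / (s * rt2)) - math.sqrt(2.0 / math.pi) * (R / s) * math.exp(
        -R * R / (2 * s * s)
    )
    out = np.where(small, a0, a) * model.contrast
    return float(out) if out.ndim == 0 else out


def continuous_threshold(d_over_fwhm: float) -> float:
    """Volume-matching relative threshold (%) in the continuous limit.

    Scale-free: depends only on the diameter-to-resolution ratio D/FWHM.
    Returns 100·A(R)/A(0).
    """
    if d_over_fwhm <= 0:
        raise ValueError("d_over_fwhm must be positive")
    model = ContinuousSphereModel(
        radius_mm=d_over_fwhm / 2.0, sigma_mm=fwhm_to_sigma(1.0)
    )
    return 100.0 * float(profile(model.radius_mm, model)) / float(profile(0.0, model))
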