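"""Closed-form threshold formulas for spherical lesions.

Two fitted branches give the volume-matching relative threshold (%) from
the lesion diameter D, the system resolution FWHM, and the reconstruction
pixel size PS (all mm):

    D < 2·FWHM:   threshold = k1 · (D/FWHM)^(−k2)                 (pixel-free)
    D ≥ 2·FWHM:   threshold = c1·exp(−c2·PS/FWHM)
                              · (1 − exp(−c3·(D/FWHM)·exp(c4·PS/FWHM)))
                              + c5·PS/FWHM

with published constants k1=46.57, k2=0.63, c1=50.568, c2=2.4758,
c3=0.4617, c4=1.658, c5=34.392, fitted over D = 2–100 mm, FWHM = 2–9 mm,
PS = FWHM/20 – FWHM/2.  Outside that domain the formulas extrapolate with
a warning.  The absolute SUV cutoff follows from the relative threshold via
the background-corrected conversion in :mod:`petthresh.thresholding`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .thresholding import absolute_from_relative

__all__ = [
    "FormulaConstants",
    "FormulaDomain",
    "PUBLISHED_CONSTANTS",
    "DOMAIN",
    "effective_pixel_size",
    "formula_threshold",
    "formula_absolute_threshold",
]


@dataclass(frozen=True)
class FormulaConstants:
    """Constants of the two threshold-formula branches (all dimensionless)."""

    k1: float = 46.57
    k2: float = 0.63
    c1: float = 50.568
    c2: float = 2.4758
    c3: float = 0.4617
    c4: float = 1.658
    c5: float = 34.392

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.as_tuple()):
            raise ValueError("all formula constants must be positive")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.k1, self.k2, self.c1, self.c2, self.c3, self.c4, self.c5)


#: The published fitted constants.
PUBLISHED_CONSTANTS = FormulaConstants()


@dataclass(frozen=True)
class FormulaDomain:
    """Validity domain of the fitted constants."""

    d_range_mm: tuple[float, float] = (2.0, 100.0)
    fwhm_range_mm: tuple[float, float] = (2.0, 9.0)
    ps_over_fwhm_range: tuple[float, float] = (1.0 / 20.0, 1.0 / 2.0)

    def contains(self, d_mm: float, fwhm_mm: float, ps_mm: float) -> bool:
        return (
            self.d_range_mm[0] <= d_mm <= self.d_range_mm[1]
            and self.fwhm_range_mm[0] <= fwhm_mm <= self.fwhm_range_mm[1]
            and self.ps_over_fwhm_range[0] - 1e-9
            <= ps_mm / fwhm_mm
            <= self.ps_over_fwhm_range[1] + 1e-9
        )


DOMAIN = FormulaDomain()


def effective_pixel_size(spacing_mm: float | tuple[float, ...]) -> float:
    """Scalar pixel size for (possibly anisotropic) voxels.

    Defined as the cube root of the voxel volume, i.e. the geometric mean of
    the three spacings; reduces to the spacing itself for isotropic voxels.
    """
    s = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if s.size == 1:
        s = np.repeat(s, 3)
    if s.size != 3:
        raise ValueError("spacing_mm must be a scalar or a 3-vector")
    if np.any(s <= 0):
        raise ValueError(f"spacings must be positive, got {spacing_mm}")
    return float(np.prod(s) ** (1.0 / 3.0))


def formula_threshold(
    d_mm: float,
    fwhm_mm: float,
    ps_mm: float | tuple[float, ...],
    constants: FormulaConstants = PUBLISHED_CONSTANTS,
) -> float:
    """Relative threshold (%) from the closed-form formulas.

    ``ps_mm`` may be a 3-vector of voxel spacings, reduced via
    :func:`effective_pixel_size`.  The small-lesion branch applies for
    D < 2·FWHM and is pixel-size independent; the branch boundary
    D = 2·FWHM uses the large-lesion branch.  Outputs above 100%
    (possible for D/FWHM below ≈0.3, outside the fitted domain) are
    clamped to 100 with a warning.
    """
    ps = effective_pixel_size(ps_mm)
    if d_mm <= 0 or fwhm_mm <= 0:
        raise ValueError("d_mm and fwhm_mm must be positive")
    if not DOMAIN.contains(d_mm, fwhm_mm, ps):
        warnings.warn(
            f"(D={d_mm}, FWHM={fwhm_mm}, PS={ps:.4g}) mm outside the fitted "
            "domain; extrapolating",
            stacklevel=2,
        )
    x = d_mm / fwhm_mm
    if x < 2.0:
        t = constants.k1 * x ** (-constants.k2)
    else:
        u = ps / fwhm_mm
        t = (
            constants.c1
            * math.exp(-constants.c2 * u)
            * (1.0 - math.exp(-constants.c3 * x * math.exp(constants.c4 * u)))
            + constants.c5 * u
        )
    if t > 100.0:
        warnings.warn(
            f"formula threshold {t:.1f}% exceeds 100%; clamping", stacklevel=2
        )
        t = 100.0
    return t


def formula_absolute_threshold(
    d_mm: float,
    fwhm_mm: float,
    ps_mm: float | tuple[float, ...],
    suvmax: float,
    suvbg: float,
    constants: FormulaConstants = PUBLISHED_CONSTANTS,
) -> float:
    """Absolute SUV cutoff: formula threshold converted with SUVmax/SUVbg."""
    t = formula_threshold(d_mm, fwhm_mm, ps_mm, constants)
    return absolute_from_relative(t, suvmax, suvbg).suv
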