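"""Relative/absolute SUV thresholds, MTV measurement, and the matching solver.

The relative threshold xx% expresses an SUV cutoff as a percentage of the
lesion contrast above background:

    absolute = (SUVmax − SUVbg) · xx%/100 + SUVbg
    xx%      = (absolute − SUVbg) / (SUVmax − SUVbg) · 100

The metabolic tumor volume (MTV) at a cutoff is the whole-voxel volume at
or above the cutoff.  The volume-matching threshold is the xx% at which the
MTV equals the true tumor volume, located by a 1-point sweep over 11–90%
followed by linear interpolation across the sign change of the volume error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume

__all__ = [
    "RelativeThreshold",
    "AbsoluteThreshold",
    "SweepRecord",
    "ThresholdResult",
    "DelineationResult",
    "absolute_from_relative",
    "relative_from_absolute",
    "measure_mtv",
    "sweep",
    "volume_matching_threshold",
    "delineate",
    "DEFAULT_SWEEP_PERCENTS",
]

logger = logging.getLogger(__name__)

#: Default sweep grid: 11%, 12%, ..., 90% (80 values).
DEFAULT_SWEEP_PERCENTS = tuple(range(11, 91))


@dataclass(frozen=True)
class RelativeThreshold:
    """Cutoff as percent of (SUVmax − SUVbg) above SUVbg."""

    percent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError(f"percent must be in [0, 100], got {self.percent}")


@dataclass(frozen=True)
class AbsoluteThreshold:
    """Cutoff in SUV units."""

    suv: float


@dataclass(frozen=True)
class SweepRecord:
    """MTV and its error against the true volume at one sweep percent."""

    percent: float
    mtv_mm3: float
    percent_error: float


@dataclass(frozen=True)
class ThresholdResult:
    """Solved volume-matching threshold for one image."""

    relative: RelativeThreshold
    absolute: AbsoluteThreshold
    matched_volume_mm3: float
    suvmax: float
    suvbg: float

    def __post_init__(self) -> None:
        back = absolute_from_relative(
            self.relative.percent, self.suvmax, self.suvbg
        ).suv
        if abs(back - self.absolute.suv) > 1e-9 * max(1.0, abs(self.suvmax)):
            raise ValueError("relative and absolute thresholds are inconsistent")


@dataclass(frozen=True)
class DelineationResult:
    """Binary target mask and its volume."""

    mask: np.ndarray
    volume_mm3: float
    absolute: AbsoluteThreshold
    suvmax: float


def absolute_from_relative(
    percent: float, suvmax: float, suvbg: float
) -> AbsoluteThreshold:
    """SUV cutoff for a relative threshold: (SUVmax−SUVbg)·xx%/100 + SUVbg."""
    if suvmax <= suvbg:
        raise ValueError(f"suvmax ({suvmax}) must exceed suvbg ({suvbg})")
    if suvbg < 0:
        raise ValueError("suvbg must be non-negative")
    return AbsoluteThreshold(suv=(suvmax - suvbg) * percent / 100.0 + suvbg)


def relative_from_absolute(
    absolute: float, suvmax: float, suvbg: float
) -> RelativeThreshold:
    """Relative threshold for an SUV cutoff; inverse of absolute_from_relative."""
    if suvmax <= suvbg:
        raise ValueError(f"suvmax ({suvmax}) must exceed suvbg ({suvbg})")
    if not suvbg <= absolute <= suvmax:
        raise ValueError(
            f"absolute threshold {absolute} outside [suvbg={suvbg}, suvmax={suvmax}]"
        )
    return RelativeThreshold(percent=(absolute - suvbg) / (suvmax - suvbg) * 100.0)


def measure_mtv(image: ImageVolume, absolute: AbsoluteThreshold | float) -> float:
    """Whole-voxel MTV: count of voxels with value ≥ cutoff, times voxel volume."""
    cutoff = absolute.suv if isinstance(absolute, AbsoluteThreshold) else float(absolute)
    count = int(np.count_nonzero(image.values >= cutoff))
    return count * image.voxel_volume_mm3


def sweep(
    image: ImageVolume,
    true_volume_mm3: float,
    suvbg: float,
    percents: tuple[float, ...] | None = None,
) -> list[SweepRecord]:
    """Measure the MTV over a grid of relative thresholds.

    ``percents`` defaults to the 80-value 11–90% grid.  Records are returned
    in sweep order; MTV is non-increasing in percent.
    """
    if percents is None:
        percents = DEFAULT_SWEEP_PERCENTS
    percents = tuple(float(p) for p in percents)
    if any(b <= a for a, b in zip(percents, percents[1:])):
        raise ValueError("percents must be strictly increasing")
    if true_volume_mm3 <= 0:
        raise ValueError("true_volume_mm3 must be positive")
    suvmax = image.suvmax
    out = []
    for p in percents:
        mtv = measure_mtv(image, absolute_from_relative(p, suvmax, suvbg))
        out.append(
            SweepRecord(
                percent=p,
                mtv_mm3=mtv,
                percent_error=(mtv - true_volume_mm3) / true_volume_mm3 * 100.0,
            )
        )
    return out


def volume_matching_threshold(
    image: ImageVolume,
    true_volume_mm3: float,
    suvbg: float,
    percents: tuple[float, ...] | None = None,
) -> ThresholdResult:
    """Solve for the relative threshold at which MTV equals the true volume.

    Sweeps the 11–90% grid (1-point steps by default), finds the first sign
    change of the volume error from low percent, and linearly interpolates
    MTV against percent across that step.  Multiple crossings (possible at
    coarse pixels, where MTV moves in whole-voxel jumps) take the first and
    log a warning.

    Raises
    ------
    ValueError
        If the true volume is not bracketed by the sweep
        ("threshold outside sweep range").
    """
    records = sweep(image, true_volume_mm3, suvbg, percents)
    errs = np.array([r.percent_error for r in records])
    ps = np.array([r.percent for r in records])
    mtvs = np.array([r.mtv_mm3 for r in records])

    exact = np.nonzero(errs == 0.0)[0]
    crossings = np.nonzero((errs[:-1] > 0) & (errs[1:] < 0))[0]
    n_solutions = len(crossings) + len(exact)
    if n_solutions == 0:
        raise ValueError(
            "threshold outside sweep range: MTV does not cross the true volume "
            f"within [{ps[0]:g}, {ps[-1]:g}]%"
        )
    if n_solutions > 1:
        logger.warning(
            "MTV crosses the true volume %d times; taking the first crossing "
            "from low percent", n_solutions,
        )

    if len(exact) and (not len(crossings) or exact[0] <= crossings[0]):
        p_star = float(ps[exact[0]])
    else:
        i = crossings[0]
        # interpolate MTV(percent) linearly across the bracketing step
        p_star = float(
            ps[i]
            + (true_volume_mm3 - mtvs[i]) * (ps[i + 1] - ps[i]) / (mtvs[i + 1] - mtvs[i])
        )
    p_star = round(p_star, 2)  # report to 0.01 pt
    suvmax = image.suvmax
    absolute = absolute_from_relative(p_star, suvmax, suvbg)
    return ThresholdResult(
        relative=RelativeThreshold(percent=p_star),
        absolute=absolute,
        matched_volume_mm3=measure_mtv(image, absolute),
        suvmax=suvmax,
        suvbg=suvbg,
    )


def delineate(
    image: ImageVolume,
    percent: float,
    suvbg: float,
    roi_center_mm: tuple[float, float, float],
    roi_radius_mm: float,
) -> DelineationResult:
    """Threshold-based target delineation inside a spherical region of interest.

    SUVmax is taken within the ROI; the cutoff is the absolute threshold for
    the given relative percent; the mask is the set of voxels at or above the
    cutoff restricted to the connected component (26-connectivity) containing
    the ROI maximum.

    Raises
    ------
    ValueError
        If the ROI covers no voxels.
    """
    if roi_radius_mm <= 0:
        raise ValueError("roi_radius_mm must be positive")
    axes = image.voxel_centers()
    c = np.asarray(roi_center_mm, dtype=float)
    d2 = (
        (axes[0] - c[0])[:, None, None] ** 2
        + (axes[1] - c[1])[None, :, None] ** 2
        + (axes[2] - c[2])[None, None, :] ** 2
    )
    roi = d2 <= roi_radius_mm**2
    if not roi.any():
        raise ValueError("ROI is empty or outside the image")

    roi_vals = np.where(roi, image.values, -np.inf)
    suvmax = float(roi_vals.max())
    seed = np.unravel_index(int(np.argmax(roi_vals)), image.values.shape)
    absolute = absolute_from_relative(percent, suvmax, suvbg)

    above = image.values >= absolute.suv
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    mask = labels == labels[seed]
    return DelineationResult(
        mask=mask,
        volume_mm3=int(mask.sum()) * image.voxel_volume_mm3,
        absolute=absolute,
        suvmax=suvmax,
    )
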