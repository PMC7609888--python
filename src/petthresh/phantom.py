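"""Ground-truth activity fields: uniform spheres in a uniform background.

A scene is a set of non-overlapping spheres of uniform tracer uptake (SUV)
embedded in a uniform background inside a rectangular field of view.
Voxelization computes, for every voxel, the fraction of its volume inside
each sphere, so the digitized field conserves the analytic tracer mass to
better than 0.1% even at coarse grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import ImageVolume

__all__ = [
    "SphereSpec",
    "SphereScene",
    "sphere_volume",
    "voxelize",
    "nema_iq_scene",
    "NEMA_SPHERE_DIAMETERS_MM",
]

#: Hot-sphere inner diameters (mm) of the image-quality phantom scene.
NEMA_SPHERE_DIAMETERS_MM = (37.0, 22.0, 17.0, 10.0)


@dataclass(frozen=True)
class SphereSpec:
    """A spherical lesion with uniform uptake.

    Parameters
    ----------
    diameter_mm : float
        Sphere diameter D in mm; must be positive.
    uptake_suv : float
        Uniform tracer uptake inside the sphere, in SUV.
    center_mm : tuple of float
        Center offset (x, y, z) in mm from the scene center.
    """

    diameter_mm: float
    uptake_suv: float
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError(f"diameter_mm must be positive, got {self.diameter_mm}")
        if len(self.center_mm) != 3:
            raise ValueError("center_mm must be a 3-vector")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    @property
    def volume_mm3(self) -> float:
        return sphere_volume(self.diameter_mm)


@dataclass(frozen=True)
class SphereScene:
    """One or more spheres plus uniform background in a field of view.

    ``fov_mm`` is the full extent (x, y, z) of the field of view, centered
    on the scene origin.  Sphere uptake must exceed the background and
    spheres must not overlap pairwise.
    """

    spheres: tuple[SphereSpec, ...]
    background_suv: float = 0.0
    fov_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "spheres", tuple(self.spheres))
        if self.background_suv < 0:
            raise ValueError("background_suv must be non-negative")
        for s in self.spheres:
            if s.uptake_suv <= self.background_suv:
                raise ValueError(
                    f"sphere uptake {s.uptake_suv} must exceed background "
                    f"{self.background_suv}"
                )
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1:]:
                gap = math.dist(a.center_mm, b.center_mm) - a.radius_mm - b.radius_mm
                if gap < 0:
                    raise ValueError(
                        f"spheres at {a.center_mm} and {b.center_mm} overlap"
                    )

    def check_margins(self, margin_mm: float) -> None:
        """Raise if any sphere is closer than ``margin_mm`` to the fov boundary."""
        half = np.asarray(self.fov_mm) / 2.0
        for s in self.spheres:
            c = np.asarray(s.center_mm)
            if np.any(np.abs(c) + s.radius_mm + margin_mm > half + 1e-9):
                raise ValueError(
                    f"sphere D={s.diameter_mm} mm at {s.center_mm} violates the "
                    f"{margin_mm:.2f} mm margin inside fov {self.fov_mm}"
                )

    @property
    def analytic_mass(self) -> float:
        """Total tracer mass above background, in SUV·mm³."""
        return sum(
            s.volume_mm3 * (s.uptake_suv - self.background_suv) for s in self.spheres
        )


def sphere_volume(diameter_mm: float) -> float:
    """Volume of a sphere of the given diameter, (π/6)·D³ in mm³."""
    if not diameter_mm > 0:
        raise ValueError(f"diameter_mm must be positive, got {diameter_mm}")
    return math.pi / 6.0 * diameter_mm**3


def _auto_subdivisions(radius: float, spacing: np.ndarray) -> int:
    """Boundary sub-grid factor for a target mass error below 0.1%.

    The antialiased estimator's curvature bias grows as the voxel becomes
    coarse relative to the sphere, so the factor steps up at small
    D/spacing ratios (empirically calibrated tiers).
    """
    ratio = 2.0 * radius / float(spacing.max())
    if ratio >= 6.0:
        return 8
    if ratio >= 2.5:
        return 24
    if ratio >= 1.2:
        return 48
    return 64


def _partial_fractions(
    axes: list[np.ndarray],
    center: np.ndarray,
    radius: float,
    spacing: np.ndarray,
    subdivisions: int | None,
) -> np.ndarray:
    """Per-voxel inside fraction for one sphere.

    Voxels are classified by center distance against radius ± half the voxel
    diagonal: strictly interior voxels get 1, exterior voxels 0, and boundary
    voxels are integrated on a ``subdivisions``³ sub-grid.  Each sub-cell
    contributes an antialiased fraction — a linear ramp of the signed
    distance to the sphere surface over the sub-cell width — rather than a
    binary in/out sample, which removes the coherent quantization error of
    point sampling on symmetric configurations.
    """
    dx2 = (axes[0] - center[0])[:, None, None] ** 2
    dy2 = (axes[1] - center[1])[None, :, None] ** 2
    dz2 = (axes[2] - center[2])[None, None, :] ** 2
    r = np.sqrt(dx2 + dy2 + dz2)

    half_diag = 0.5 * float(np.linalg.norm(spacing))
    frac = np.zeros(r.shape, dtype=np.float64)
    frac[r <= radius - half_diag] = 1.0

    boundary = (r > radius - half_diag) & (r < radius + half_diag)
    idx = np.argwhere(boundary)
    if idx.size == 0:
        return frac

    n = subdivisions if subdivisions is not None else _auto_subdivisions(
        radius, spacing
    )
    off1d = (np.arange(n) + 0.5) / n - 0.5  # cell-center offsets in voxel units
    ox, oy, oz = np.meshgrid(off1d, off1d, off1d, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1) * spacing

    centers = np.stack(
        [axes[0][idx[:, 0]], axes[1][idx[:, 1]], axes[2][idx[:, 2]]], axis=1
    ) - center[None, :]
    sub_width = float(spacing.max()) / n
    # chunk to bound memory: N_boundary × n³ distance evaluations
    chunk = max(1, int(4e7) // offsets.shape[0])
    fractions = np.empty(len(idx), dtype=np.float64)
    for lo in range(0, len(idx), chunk):
        sub = centers[lo:lo + chunk, None, :] + offsets[None, :, :]
        dist = np.sqrt((sub**2).sum(axis=2))
        fractions[lo:lo + chunk] = np.clip(
            0.5 + (radius - dist) / sub_width, 0.0, 1.0
        ).mean(axis=1)
    frac[idx[:, 0], idx[:, 1], idx[:, 2]] = fractions
    return frac


def voxelize(
    scene: SphereScene,
    grid_spacing_mm: float | tuple[float, float, float],
    subdivisions: int | None = None,
    shape: tuple[int, int, int] | None = None,
) -> ImageVolume:
    """Digitize a scene onto a regular grid with partial-volume fractions.

    Each voxel receives ``background + Σ (uptake − background)·f`` where *f*
    is the fraction of the voxel inside the sphere.  The grid is centered on
    the scene origin; voxel centers sit at ``origin + (index + 0.5)·spacing``.
    Total tracer mass matches the analytic value within 0.1% for any
    diameter-to-spacing ratio ≥ 1.

    Parameters
    ----------
    scene : SphereScene
    grid_spacing_mm : float or 3-tuple
        Isotropic or per-axis voxel spacing.
    subdivisions : int, optional
        Sub-grid factor for boundary voxels; by default chosen adaptively
        from the diameter-to-spacing ratio (8³ on fine grids, up to 64³ for
        spheres close to one voxel).
    shape : tuple, optional
        Explicit grid shape; by default the smallest grid covering the fov.

    Raises
    ------
    ValueError
        If a sphere extends outside the field of view.
    """
    spacing = np.broadcast_to(np.asarray(grid_spacing_mm, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("grid_spacing_mm must be positive")
    fov = np.asarray(scene.fov_mm, dtype=float)
    if shape is None:
        shape = tuple(int(math.ceil(f / s - 1e-9)) for f, s in zip(fov, spacing))
    if any(n <= 0 for n in shape):
        raise ValueError(f"empty grid for fov {scene.fov_mm}")
    half = np.asarray(shape) * spacing / 2.0
    for s in scene.spheres:
        c = np.asarray(s.center_mm)
        if np.any(np.abs(c) + s.radius_mm > half + 1e-9):
            raise ValueError(
                f"sphere D={s.diameter_mm} mm at {s.center_mm} extends outside "
                f"the fov {scene.fov_mm}"
            )

    origin = -half
    axes = [
        origin[a] + (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)
    ]
    values = np.full(shape, scene.background_suv, dtype=np.float64)
    for s in scene.spheres:
        f = _partial_fractions(
            axes, np.asarray(s.center_mm, dtype=float), s.radius_mm, spacing,
            subdivisions,
        )
        values += (s.uptake_suv - scene.background_suv) * f
    return ImageVolume(values=values, spacing_mm=tuple(spacing), origin_mm=tuple(origin))


def nema_iq_scene(
    contrast_ratio: float,
    background_suv: float,
    ring_radius_mm: float = 57.2,
    fov_margin_mm: float = 20.0,
) -> SphereScene:
    """Four-hot-sphere scene modeled on the NEMA image-quality phantom.

    Spheres of diameter 37, 22, 17 and 10 mm lie coplanar on a ring (default
    radius 57.2 mm, as in the physical phantom) at 90° spacing, with uptake
    ``contrast_ratio × background_suv``.  The spacing keeps blurred spheres
    from overlapping for system FWHM up to 9 mm.
    """
    if contrast_ratio <= 1:
        raise ValueError("contrast_ratio must exceed 1")
    if background_suv <= 0:
        raise ValueError(
            "background_suv must be positive (sphere uptake is contrast × background)"
        )
    uptake = contrast_ratio * background_suv
    angles = np.deg2rad([0.0, 90.0, 180.0, 270.0])
    spheres = tuple(
        SphereSpec(
            diameter_mm=d,
            uptake_suv=uptake,
            center_mm=(
                ring_radius_mm * math.cos(a),
                ring_radius_mm * math.sin(a),
                0.0,
            ),
        )
        for d, a in zip(NEMA_SPHERE_DIAMETERS_MM, angles)
    )
    r_max = max(NEMA_SPHERE_DIAMETERS_MM) / 2.0
    xy = 2.0 * (ring_radius_mm + r_max + fov_margin_mm)
    z = 2.0 * (r_max + fov_margin_mm)
    return SphereScene(
        spheres=spheres, background_suv=background_suv, fov_mm=(xy, xy, z)
    )
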