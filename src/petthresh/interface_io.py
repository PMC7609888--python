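"""I/O plumbing: NIfTI volumes, scene/config JSON-YAML, CSV tables, fixtures.

Volumes travel as NIfTI-1 (the lingua franca of research PET tooling):
values as float32, masks as uint8, voxel spacing in the affine.  Only
axis-aligned volumes are supported.  Threshold tables are plain CSV.  The
fixture generator emits a synthetic image-quality-phantom scene plus
reference tables for offline comparison.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .imaging import ImageVolume, SystemModel, simulate
from .phantom import SphereScene, SphereSpec, nema_iq_scene, voxelize
from .experiments import GridConfig, GridRecord, records_to_dataframe, run_grid

__all__ = [
    "read_volume",
    "write_volume",
    "scene_to_dict",
    "scene_from_dict",
    "read_scene",
    "write_scene",
    "grid_config_from_dict",
    "read_grid_config",
    "write_grid_csv",
    "read_grid_csv",
    "load_table1_reference",
    "load_table2_reference",
    "make_fixtures",
]

logger = logging.getLogger(__name__)

GRID_CSV_COLUMNS = (
    "d_mm", "fwhm_mm", "ps_mm", "bg_fraction", "threshold_percent", "suvmax",
)


# ---------------------------------------------------------------- NIfTI I/O

def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; float32 for images, uint8 for boolean masks."""
    path = Path(path)
    data = volume.values
    dtype = np.uint8 if data.dtype == bool else np.float32
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing_mm)
    # NIfTI maps indices to voxel centers; ours sit at origin + (i + 0.5)·spacing
    affine[:3, 3] = np.asarray(volume.origin_mm) + 0.5 * np.asarray(volume.spacing_mm)
    img = nib.Nifti1Image(data.astype(dtype), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> ImageVolume:
    """Read an axis-aligned NIfTI-1 volume.

    Raises
    ------
    ValueError
        For non-NIfTI input or oblique (non-axis-aligned) affines.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise ValueError(f"{path} is not a NIfTI file (got {type(img).__name__})")
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError(f"{path}: oblique affine; only axis-aligned volumes supported")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: degenerate voxel spacing in affine")
    origin = affine[:3, 3] - 0.5 * spacing
    values = np.asanyarray(img.dataobj).astype(np.float64)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {values.shape}")
    return ImageVolume(
        values=values, spacing_mm=tuple(spacing), origin_mm=tuple(origin)
    )


# ------------------------------------------------------- scene / config I/O

def scene_to_dict(scene: SphereScene) -> dict:
    return {
        "background_suv": scene.background_suv,
        "fov_mm": list(scene.fov_mm),
        "spheres": [
            {
                "diameter_mm": s.diameter_mm,
                "uptake_suv": s.uptake_suv,
                "center_mm": list(s.center_mm),
            }
            for s in scene.spheres
        ],
    }


def scene_from_dict(d: dict) -> SphereScene:
    return SphereScene(
        spheres=tuple(
            SphereSpec(
                diameter_mm=s["diameter_mm"],
                uptake_suv=s["uptake_suv"],
                center_mm=tuple(s.get("center_mm", (0.0, 0.0, 0.0))),
            )
            for s in d["spheres"]
        ),
        background_suv=d.get("background_suv", 0.0),
        fov_mm=tuple(d["fov_mm"]),
    )


def write_scene(scene: SphereScene, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(scene_to_dict(scene), indent=2) + "\n")
    return path


def read_scene(path: str | Path) -> SphereScene:
    return scene_from_dict(json.loads(Path(path).read_text()))


def grid_config_from_dict(d: dict) -> GridConfig:
    """Build a grid config from a mapping; unknown keys are rejected."""
    allowed = {f.name for f in dataclasses.fields(GridConfig)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown grid config keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d.items()}
    return GridConfig(**kwargs)


def read_grid_config(path: str | Path) -> GridConfig:
    """Read a grid config from YAML or JSON."""
    text = Path(path).read_text()
    return grid_config_from_dict(yaml.safe_load(text) or {})


# ----------------------------------------------------------------- CSV I/O

def write_grid_csv(records: list[GridRecord], path: str | Path) -> Path:
    path = Path(path)
    df = records_to_dataframe(records)[list(GRID_CSV_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    return path


def read_grid_csv(path: str | Path) -> list[GridRecord]:
    df = pd.read_csv(path)
    missing = set(GRID_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"grid CSV {path} missing columns {sorted(missing)}")
    return [
        GridRecord(
            d_mm=float(r.d_mm),
            fwhm_mm=float(r.fwhm_mm),
            ps_mm=float(r.ps_mm),
            bg_fraction=float(r.bg_fraction),
            threshold_percent=float(r.threshold_percent),
            suvmax=float(r.suvmax),
        )
        for r in df.itertuples()
    ]


def _load_reference(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("petthresh").joinpath("data", name)
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def load_table1_reference() -> pd.DataFrame:
    """Published typical thresholds vs D/FWHM (reference data, not an oracle)."""
    return _load_reference("reference_thresholds_vs_d_over_fwhm.csv")


def load_table2_reference() -> pd.DataFrame:
    """Published phantom-validation table: sphere volumes and formula thresholds."""
    return _load_reference("reference_phantom_validation.csv")


# ---------------------------------------------------------------- fixtures

#: Validation-scan geometry: voxel size and post-filter FWHM of the phantom scan.
VALIDATION_VOXEL_MM = (3.65, 3.65, 3.27)
VALIDATION_FWHM_MM = 8.0
VALIDATION_CONTRAST = 8.0


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Generate the synthetic validation fixture set.

    Writes (a) the simulated four-sphere image-quality scene at 8 mm FWHM on
    the validation voxel grid with 8:1 contrast, (b) per-sphere ground-truth
    masks on the same grid, (c) a reduced simulated threshold grid as CSV,
    and (d) the published reference tables.  Fully deterministic; ``seed``
    is recorded in the manifest for provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    scene = nema_iq_scene(
        contrast_ratio=VALIDATION_CONTRAST, background_suv=1.0
    )
    paths["scene"] = write_scene(scene, out_dir / "nema_scene.json")
    system = SystemModel(fwhm_mm=VALIDATION_FWHM_MM, pixel_mm=VALIDATION_VOXEL_MM)
    image = simulate(scene, system)
    paths["image"] = write_volume(image, out_dir / "nema_image.nii.gz")

    for sphere in scene.spheres:
        truth = voxelize(
            SphereScene(
                spheres=(
                    SphereSpec(
                        diameter_mm=sphere.diameter_mm,
                        uptake_suv=1.0,
                        center_mm=sphere.center_mm,
                    ),
                ),
                background_suv=0.0,
                fov_mm=scene.fov_mm,
            ),
            image.spacing_mm,
            shape=image.values.shape,
        )
        mask = ImageVolume(
            values=truth.values >= 0.5,
            spacing_mm=image.spacing_mm,
            origin_mm=image.origin_mm,
        )
        key = f"mask_d{sphere.diameter_mm:g}"
        paths[key] = write_volume(mask, out_dir / f"nema_{key}.nii.gz")

    reduced = GridConfig(
        diameters_mm=(4.0, 8.0, 16.0, 32.0),
        fwhms_mm=(4.0,),
        ps_fractions=(1 / 10, 1 / 4),
        background_fractions=(0.0, 0.5),
    )
    records = run_grid(reduced)
    paths["grid_csv"] = write_grid_csv(records, out_dir / "reduced_grid.csv")

    for key, loader, name in (
        ("table1", load_table1_reference, "reference_thresholds_vs_d_over_fwhm.csv"),
        ("table2", load_table2_reference, "reference_phantom_validation.csv"),
    ):
        df = loader()
        p = out_dir / name
        df.to_csv(p, index=False, lineterminator="\n")
        paths[key] = p

    manifest = {
        "seed": seed,
        "fwhm_mm": VALIDATION_FWHM_MM,
        "voxel_mm": list(VALIDATION_VOXEL_MM),
        "contrast_ratio": VALIDATION_CONTRAST,
        "files": {k: p.name for k, p in paths.items()},
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = mpath
    return paths
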