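import numpy as np
import pytest

import petthresh as pt


@pytest.fixture(scope="session")
def sphere_image_bg0():
    """Simulated D=8 mm sphere, FWHM 4 mm, PS 1 mm, no background."""
    scene = pt.single_sphere_scene(8.0, 4.0, 1.0, bg_fraction=0.0)
    return pt.simulate(scene, pt.SystemModel(fwhm_mm=4.0, pixel_mm=1.0))


@pytest.fixture(scope="session")
def sphere_image_bg_half():
    """Same geometry with background at half the lesion uptake (SUVbg 5)."""
    scene = pt.single_sphere_scene(8.0, 4.0, 1.0, bg_fraction=0.5)
    return pt.simulate(scene, pt.SystemModel(fwhm_mm=4.0, pixel_mm=1.0))


@pytest.fixture(scope="session")
def step_sphere_image():
    """Unblurred voxelized D=10 mm sphere (uptake 10) on a 0.5 mm grid."""
    scene = pt.SphereScene(
        spheres=(pt.SphereSpec(diameter_mm=10.0, uptake_suv=10.0),),
        background_suv=0.0,
        fov_mm=(16.0, 16.0, 16.0),
    )
    return pt.voxelize(scene, 0.5)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Generated synthetic validation fixture set (phantom scene et al.)."""
    out = tmp_path_factory.mktemp("fixtures")
    paths = pt.make_fixtures(out, seed=0)
    return paths
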