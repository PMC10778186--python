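import numpy as np
import pytest

from hyperskin.calibration import fit_correction_matrix
from hyperskin.cie_color import load_cmf, srgb_to_xyz_array
from hyperskin.classify import samples_from_dataset
from hyperskin.spectral_model import fit_spectral_basis, fit_transformation_matrix
from hyperskin.synthetic_data import (
    CameraModel,
    SceneSpec,
    default_illuminant,
    generate_checker_scene,
    generate_lesion_dataset,
)


@pytest.fixture(scope="session")
def cmf():
    return load_cmf()


@pytest.fixture(scope="session")
def illuminant():
    return default_illuminant()


def calibrate_scene(scene):
    """Fit (correction matrix, spectral basis with M) from a checker scene."""
    cam_xyz = srgb_to_xyz_array(scene.camera_rgb.astype(float))
    calib = fit_correction_matrix(cam_xyz, scene.true_xyz)
    basis = fit_spectral_basis(scene.spectra, 12)
    basis = fit_transformation_matrix(basis, scene.true_xyz)
    return calib, basis


@pytest.fixture(scope="session")
def ideal_scene(cmf):
    """Checker scene shot by a distortion-free camera."""
    return generate_checker_scene(seed=0, cam=CameraModel.ideal(), cmf=cmf)


@pytest.fixture(scope="session")
def ideal_calibration(ideal_scene):
    return calibrate_scene(ideal_scene)


@pytest.fixture(scope="session")
def study_camera():
    """The default study camera: cubic tone curve, dark offset, chroma noise."""
    return CameraModel()


@pytest.fixture(scope="session")
def study_scene(cmf, study_camera):
    return generate_checker_scene(seed=0, cam=study_camera, cmf=cmf)


@pytest.fixture(scope="session")
def study_calibration(study_scene):
    return calibrate_scene(study_scene)


@pytest.fixture(scope="session")
def lesion_dataset(cmf):
    """Default-condition lesion dataset: 20 patients x 10 images, seed 0."""
    return generate_lesion_dataset(SceneSpec(seed=0), cmf)


@pytest.fixture(scope="session")
def lesion_samples(lesion_dataset, study_calibration):
    calib, basis = study_calibration
    return samples_from_dataset(lesion_dataset, calib, basis)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
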