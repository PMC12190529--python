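import numpy as np
import pytest

import nbisim as nb
from nbisim import calibration as calib
from nbisim import colorimetry as cm
from nbisim import nbi, spectral, synth


@pytest.fixture(scope="session")
def grid():
    return nb.SpectralGrid()


@pytest.fixture(scope="session")
def cmf(grid):
    return cm.cmf_1931(grid)


@pytest.fixture(scope="session")
def illuminant(grid):
    return cm.d65_illuminant(grid)


class World:
    """A fully fitted synthetic study: 24 smooth patches, mildly nonlinear
    camera, calibration + spectral models, reconstructed patch spectra."""

    def __init__(self, grid, cmf, illuminant, refl_seed=1, cam_seed=2,
                 distortion_degree=2, reflectances=None, k=6):
        self.grid, self.cmf, self.illuminant = grid, cmf, illuminant
        if reflectances is None:
            reflectances = synth.gen_reflectances(24, grid, seed=refl_seed)
        self.R = reflectances
        self.camera = synth.gen_camera(
            grid, seed=cam_seed, distortion_degree=distortion_degree, cmf=cmf
        )
        self.scene = synth.SyntheticScene(grid, self.R)
        self.wli, self.true_xyz = synth.render_wli(
            self.scene, self.camera, illuminant, cmf
        )
        self.patch_rgb = np.asarray(cm.srgb_encode(self.camera.respond(self.true_xyz)))
        self.cal = calib.PatchCalibrationSet(grid, self.patch_rgb, self.R)
        self.model = calib.fit_correction(self.cal, illuminant=illuminant, cmf=cmf)
        self.basis = spectral.fit_basis(self.R, grid, k=k)
        self.mapping = spectral.fit_mapping(self.basis, self.cal, self.model)
        self.corrected = calib.apply_correction(
            self.model, calib.camera_xyz_from_srgb(self.patch_rgb)
        )
        self.recon = spectral.reconstruct_spectrum(
            self.mapping, self.basis, self.corrected
        )


@pytest.fixture(scope="session")
def world(grid, cmf, illuminant):
    """The default study world (reflectance seed 1, camera seed 2)."""
    return World(grid, cmf, illuminant)


@pytest.fixture(scope="session")
def exact_world(grid, cmf, illuminant):
    """Noiseless world with rank-3 reflectances and a quadratic camera whose
    nonlinearity the default expansion inverts exactly."""
    R = synth.gen_lowrank_reflectances(24, grid, dim=3, seed=11)
    return World(grid, cmf, illuminant, cam_seed=12, reflectances=R, k=3)


@pytest.fixture(scope="session")
def band_spec():
    return nbi.default_band_spec()
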