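import numpy as np
import pytest

from nanomap import optics, synth


@pytest.fixture(scope="session")
def dlil_geometry():
    """The screening-geometry default: beta=67 deg, f=10 mm, 325 nm."""
    return optics.InterferometerGeometry()


@pytest.fixture(scope="session")
def dlil_profile(dlil_geometry):
    return optics.build_topography_profile(dlil_geometry, n_samples=200)


@pytest.fixture(scope="session")
def exp_profile():
    """Exactly log-linear 0.2-20 um gradient over 1 cm."""
    return optics.exponential_profile(0.2, 20.0, length_um=10000.0,
                                      n_samples=200)


@pytest.fixture(scope="session")
def exp_calibration(exp_profile):
    return optics.fit_size_calibration(exp_profile)


@pytest.fixture()
def growth_model():
    return synth.ResponseModel("axonal_growth", peak_size_um=5.0,
                               noise_sd=0.1)


@pytest.fixture()
def growth_scene(exp_profile, growth_model):
    return synth.make_scene(exp_profile, growth_model,
                            density_per_cm2=10000.0, void_fraction=0.3,
                            seed=11)
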