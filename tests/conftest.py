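import numpy as np
import pytest

from pkdvol.cohort import load_cohort
from pkdvol.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def cohort():
    return load_cohort()


@pytest.fixture(scope="session")
def lopsided_phantom():
    """Default-condition lopsided phantom with ground truth (seed 17)."""
    return generate_phantom(PhantomSpec(pattern="lopsided", seed=17))


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Noise-free two-mode phantom: modes known by construction."""
    return generate_phantom(PhantomSpec(pattern="typical_bilateral", noise_sd=0.0, seed=5))


@pytest.fixture(scope="session")
def ellipsoid_truth_1mm():
    """Two cyst-free ellipsoidal kidneys, semiaxes (40, 25, 25) mm, 1 mm grid."""
    spec = PhantomSpec(
        grid_shape=(240, 72, 72),
        voxel_spacing=(1.0, 1.0, 1.0),
        kidney_semiaxes=(40.0, 25.0, 25.0),
        n_cysts=0,
        blur_sigma=0.0,
        noise_sd=0.0,
        seed=1,
    )
    return generate_phantom(spec)


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(test_seed)
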