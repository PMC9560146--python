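import numpy as np
import pytest

from dscfrac import AcquisitionParams, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def small_acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, leak-free phantom on a small grid (construction = truth)."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 12),
        lesion_fraction_hyper=0.4,
        noise_sigma=0.0,
        k2_leakage=0.0,
        lesion_radius_mm=10.0,
        seed=11,
    )
    return build_phantom(spec)


@pytest.fixture(scope="session")
def leaky_phantom():
    """Noise-free phantom with unidirectional leakage in enhancing voxels."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 12),
        lesion_fraction_hyper=0.4,
        noise_sigma=0.0,
        k2_leakage=0.02,
        lesion_radius_mm=10.0,
        seed=11,
    )
    return build_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
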