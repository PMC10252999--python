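import numpy as np
import pytest

from vesseliq import KernelSpec, PhantomSpec, generate_vessel_image


@pytest.fixture
def noiseless_kernel() -> KernelSpec:
    """A quiet, moderately blurred reconstruction for geometry tests."""
    return KernelSpec("Br", 36, psf_sigma=0.3, noise_sd=0.0,
                      attenuation_bias=0.0)


@pytest.fixture
def noiseless_disk(noiseless_kernel):
    """Noiseless 3.5 mm vessel phantom image, centred in a 19.2 mm FOV."""
    spec = PhantomSpec(vessel_diameter=3.5, kernel=noiseless_kernel, seed=0)
    return spec, generate_vessel_image(spec)


def make_profile_grid(lo=-5.0, hi=8.0, step=0.1) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)
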