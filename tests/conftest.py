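import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from ivm_microflow.synthetic_data import (
    VesselFieldParams,
    generate_vessel_field,
)


@pytest.fixture(scope="session")
def noise_free_field():
    """One noise-free three-vessel field plus its ground truth."""
    params = VesselFieldParams(n_segments=3, noise_sd=0.0)
    stack, fov = generate_vessel_field(params, seed=7)
    return params, stack, fov


@pytest.fixture(scope="session")
def single_perfused_field():
    """A single perfused tube with known diameter and velocity."""
    params = VesselFieldParams(
        n_segments=1,
        perfused_fraction=1.0,
        diameter_range_um=(12.0, 12.0),
        velocity_range_um_s=(500.0, 500.0),
        noise_sd=0.0,
    )
    stack, fov = generate_vessel_field(params, seed=3)
    return params, stack, fov


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
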