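import numpy as np
import pytest

from speckleflow import PhantomSpec, simulate_stack


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """64x64, 15-frame, n_eff=16, sharp-boundary phantom used across tests."""
    spec = PhantomSpec(height=64, width=64, vessel_width_px=16, n_eff=16, seed=7)
    stack, gt = simulate_stack(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def deep_phantom():
    """Same geometry at depth-blur sigma 4 (deep-vessel conditions)."""
    spec = PhantomSpec(
        height=64, width=64, vessel_width_px=16, n_eff=16, depth_blur_sigma=4.0, seed=11
    )
    stack, gt = simulate_stack(spec)
    return spec, stack, gt
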