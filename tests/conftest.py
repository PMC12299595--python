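import numpy as np
import pytest

import cestpipe as cp


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, B0-free 32x32 phantom: the oracle-equivalence setting."""
    spec = cp.PhantomSpec(noise_sd=0.0, b0_amplitude_ppm=0.0)
    aptw_stack, wassr_stack, truth = cp.build_phantom(spec, seed=11)
    return spec, aptw_stack, wassr_stack, truth


@pytest.fixture(scope="session")
def shifted_phantom():
    """Noiseless phantom with a smooth +/-0.3 ppm B0 field."""
    spec = cp.PhantomSpec(noise_sd=0.0, b0_amplitude_ppm=0.3)
    aptw_stack, wassr_stack, truth = cp.build_phantom(spec, seed=12)
    return spec, aptw_stack, wassr_stack, truth


@pytest.fixture()
def water_pool():
    return cp.PoolSpec(0.0, 0.9, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
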