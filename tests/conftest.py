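import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def impulse_kernel():
    """Identity kernel: convolution with it is the identity map."""
    from vbcca.hrf import HRFKernel

    return HRFKernel(
        samples=np.array([1.0, 0.0, 0.0]), dt=1.0, peak_time=0.0, undershoot_time=0.0
    )
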