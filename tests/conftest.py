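import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_kernel():
    from visioneq.model import KernelSpec

    return KernelSpec(family="gaussian", scale=2.0, support_radius=5.0, normalize=True)
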