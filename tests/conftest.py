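import numpy as np
import pytest

from renofib.synthetic import PhantomSpec, gen_dwi_phantom, gen_ir_phantom


@pytest.fixture
def noiseless_spec():
    return PhantomSpec(rician_sigma=0.0, seed=0)


@pytest.fixture
def noiseless_dwi(noiseless_spec):
    return gen_dwi_phantom(noiseless_spec)


@pytest.fixture
def noiseless_ir(noiseless_spec):
    return gen_ir_phantom(noiseless_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
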