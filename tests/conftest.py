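import numpy as np
import pytest

import cutmeta as cm
from cutmeta.datasets import load_apgar, load_microvessel


@pytest.fixture(scope="session")
def apgar():
    return load_apgar()


@pytest.fixture(scope="session")
def microvessel():
    return load_microvessel()


@pytest.fixture(scope="session")
def apgar_blocks(apgar):
    return cm.assemble_blocks(apgar)


@pytest.fixture(scope="session")
def microvessel_blocks(microvessel):
    return cm.assemble_blocks(microvessel)


@pytest.fixture(scope="session")
def apgar_mv(apgar, apgar_blocks):
    return cm.fit_mv(apgar_blocks, levels=apgar.registry.labels)


@pytest.fixture(scope="session")
def microvessel_mv(microvessel, microvessel_blocks):
    return cm.fit_mv(microvessel_blocks, levels=microvessel.registry.labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
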