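import numpy as np
import pytest

from ctphase import ExtractorConfig, PhaseNet
from ctphase.phantom import EnhancementProfile, PhantomSpec


@pytest.fixture(scope="session")
def spec32():
    return PhantomSpec(shape=(32, 32, 32))


@pytest.fixture(scope="session")
def profile():
    return EnhancementProfile()


@pytest.fixture()
def net16():
    """Tiny untrained 3-class network on 16-cubed inputs (fast unit tests)."""
    return PhaseNet(ExtractorConfig.desk((16, 16, 16)), n_classes=3, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
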