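import numpy as np
import pytest

from paleodect.calibration import build_calcium_basis, build_fluorine_basis


@pytest.fixture(scope="session")
def fluorine_basis():
    return build_fluorine_basis()


@pytest.fixture(scope="session")
def calcium_basis():
    return build_calcium_basis()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220930)
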