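import numpy as np
import pytest

from hepaclear import CONTROL_TRUTH, DispersionContext


@pytest.fixture
def control_ctx() -> DispersionContext:
    """Dispersion context for the control group (rat physiology)."""
    return DispersionContext(fu_p=0.0078, r_b=3.95)


@pytest.fixture
def repeated_ctx() -> DispersionContext:
    """Dispersion context for the repeated-dosing group."""
    return DispersionContext(fu_p=0.0078, r_b=4.53)


@pytest.fixture
def control_truth():
    return CONTROL_TRUTH


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
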