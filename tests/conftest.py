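import numpy as np
import pytest

import hierchaos as hc


@pytest.fixture(scope="session")
def rule():
    return hc.QuadratureRule.gauss_hermite(101)


@pytest.fixture(scope="session")
def small_micro_net():
    """Small chaotic two-level network (microscopic phase)."""
    return hc.build_two_level(n=20, P=10, sigma=4.0, sigma_mu=0.5, seed=42)


@pytest.fixture(scope="session")
def small_macro_net():
    """Small two-level network in the macroscopic-chaos phase."""
    return hc.build_two_level(n=20, P=10, sigma=1.0, sigma_mu=5.0, seed=43)


@pytest.fixture(scope="session")
def grid():
    return np.linspace(-6.0, 6.0, 241)
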