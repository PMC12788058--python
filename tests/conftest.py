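import numpy as np
import pytest
from scipy.optimize import brentq

from wspri.optics import kretschmann_stack, true_rw


@pytest.fixture(scope="session")
def default_stack():
    """The packaged sensor: prism 1.785 / Cr 2 nm / Au 48 nm / analyte."""
    return kretschmann_stack()


@pytest.fixture(scope="session")
def dip_to_ri(default_stack):
    """Invert the forward model: analyte RI whose dense-grid dip is at a target.

    Uses a wide search window so dips near the LED-window edges stay
    resolvable during the root find.
    """

    def rw_of_n(n: float) -> float:
        return true_rw(
            default_stack.with_analyte_index(n), search_range_nm=(700.0, 900.0)
        )

    def invert(target_nm: float) -> float:
        return brentq(
            lambda n: rw_of_n(n) - target_nm, 1.3140, 1.3460, xtol=1e-10
        )

    invert.rw_of_n = rw_of_n
    return invert


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
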