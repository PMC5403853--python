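import numpy as np
import pytest

import mrcosim as m


@pytest.fixture
def decay_problem():
    """Stiff scalar test problem dx/dt = -50 x + sin(t) with exact solution."""
    lam = 50.0

    def rhs(t, x, u=None):
        return -lam * x + np.sin(t)

    def exact(t, x0=1.0):
        # particular solution Im(e^{it}/(i + lam)), homogeneous decay
        xp = (lam * np.sin(t) - np.cos(t)) / (lam**2 + 1.0)
        xp0 = -1.0 / (lam**2 + 1.0)
        return (x0 - xp0) * np.exp(-lam * t) + xp

    return rhs, exact, lam


@pytest.fixture
def synthetic_smooth():
    """Synthetic two-rate problem without pulses (closed form available)."""
    return m.make_synthetic_problem(pulse_amplitude=0.0)
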