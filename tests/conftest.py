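import numpy as np
import pytest

import vesipinch as vp


@pytest.fixture(scope="session")
def ref_state():
    """Bare vesicle: C0 = Sigma = DeltaP = 0, Lambda = 1, Gamma = 3."""
    return vp.state_from_groups(0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def series6():
    """Order-6 neck series, derived once per session."""
    return vp.derive_series(6)


@pytest.fixture(scope="session")
def series4():
    return vp.derive_series(4)


@pytest.fixture(scope="session")
def ref_exact_sweep(ref_state):
    """Reference exact-tier pathway, shared across tests (expensive)."""
    from vesipinch.observables import exact_sweep
    s_grid = np.concatenate([[0.0], np.arange(0.05, 0.9, 0.05),
                             [0.9, 0.92, 0.95]])
    return exact_sweep(ref_state, s_grid)


def state_for(Lambda, Gamma):
    """Realize a (Lambda, Gamma) pair with zero spontaneous curvature."""
    return vp.state_from_groups(0.0, (Gamma - 3.0) / 2.0, Lambda - Gamma + 2.0)
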