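import numpy as np
import pytest

from eicpg.params import NetworkParams

G_TOT_REF = float(np.sqrt(2 * 1.5**2))  # g_E = g_I = 1.5


@pytest.fixture
def balanced_params():
    """Symmetric two-population network at the reference coupling."""
    return NetworkParams(n_exc=375, n_inh=375, p_exc=0.1, p_inh=0.1,
                         g_exc=1.5, g_inh=1.5, seed=42)


@pytest.fixture
def tiny_params():
    """Small network for fast dynamical tests."""
    return NetworkParams(n_exc=30, n_inh=30, p_exc=0.2, p_inh=0.2,
                         g_exc=1.0, g_inh=1.0, n_outputs=3, seed=7)
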