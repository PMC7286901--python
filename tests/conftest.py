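import numpy as np
import pytest

from bufferscan import SimParams


@pytest.fixture
def chase_params():
    """Arrest-chase parameters used throughout: 1000 µM template, 1 mM
    inhibitor dosed at 300 s, degradation fixed at 0.01 s^-1."""
    return SimParams(k_trans=0.01, k_f=0.03, k_deg=0.01, k_block=10.0,
                     S0=1000.0, I_dose=1000.0, t_arrest=300.0)


@pytest.fixture
def t_grid():
    return np.linspace(0.0, 1200.0, 601)
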