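import numpy as np
import pytest
from hypothesis import settings

from pmfbind import DoubleWell, SimConfig, generate_window_set

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def binding_well():
    """A single smooth binding well that decays to zero in bulk."""
    return DoubleWell(depth1=6.0, center1=2.0, depth2=0.0, center2=6.0,
                      width=1.2, barrier=0.0, z_lo=-2.0, z_hi=12.0)


@pytest.fixture(scope="session")
def small_window_set(binding_well):
    """Modest umbrella dataset shared by WHAM/uncertainty unit tests:
    8 windows over [0, 10.5], ~2.7k production samples per window,
    3 ps between saved points."""
    cfg = SimConfig(seed=42, diffusion=0.1, dt=0.005, n_steps=3000 * 600,
                    s_save=600)
    return generate_window_set(binding_well, 0.0, 10.5, 1.5, 4.0, cfg)


@pytest.fixture(scope="session")
def small_edges():
    return np.arange(-0.5, 11.251, 0.25)
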