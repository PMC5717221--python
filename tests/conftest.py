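import numpy as np
import pytest

import lgca_walks as lw


@pytest.fixture(scope="session")
def cs4():
    return lw.build_channel_set(4)


@pytest.fixture(scope="session")
def cs2():
    return lw.build_channel_set(2)


@pytest.fixture(scope="session")
def scales16():
    """Paper-style scales: v=16, D_rw=1 -> eps=0.25, tau=0.015625."""
    return lw.Scales.from_speed_and_diffusion(16.0, 1.0, d=2)


@pytest.fixture(scope="session")
def scales10():
    """v=10, D_rw=1 -> tau=0.04 (> typical Delta, kernel valid from k=1)."""
    return lw.Scales.from_speed_and_diffusion(10.0, 1.0, d=2)


@pytest.fixture(scope="session")
def small_persistent(cs4, scales16):
    mc = lw.ModelConfig(model="persistent", channels=cs4, scales=scales16, beta=5.0)
    return lw.simulate_ensemble(mc, 500, 40, seed=7)


@pytest.fixture(scope="session")
def small_classical(cs4, scales16):
    mc = lw.ModelConfig(model="classical", channels=cs4, scales=scales16)
    return lw.simulate_ensemble(mc, 500, 40, seed=8)
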