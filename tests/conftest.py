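import numpy as np
import pytest

import lcd_llps as m


@pytest.fixture(scope="session")
def wt():
    return m.build_variant("WT")


@pytest.fixture(scope="session")
def pm2():
    return m.build_variant("2PM")


@pytest.fixture(scope="session")
def pm4():
    return m.build_variant("4PM")


@pytest.fixture(scope="session")
def model0():
    """Default interaction model at 0 mM NaCl (buffer only)."""
    return m.InteractionModel(c_nacl=0.0)


@pytest.fixture(scope="session")
def small_state(wt, model0):
    """A reproducible 3-chain system in a 20 nm cube."""
    return m.initialize_system(wt, 3, (20.0, 20.0, 20.0), seed=7,
                               temperature=model0.temperature)

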