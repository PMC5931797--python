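import numpy as np
import pytest
from hypothesis import settings

import accdecode as ad

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def geometry():
    return ad.build_track_geometry()


@pytest.fixture(scope="session")
def tiny_session():
    """8 units, 2 blocks (32 trials): the fast fixture behind most tests."""
    cfg = ad.SimulatorConfig()
    cfg.schedule.blocks = cfg.schedule.blocks[:2]
    cfg.tuning.n_units = 8
    cfg.excursions.mode = "none"
    return ad.make_session(cfg, seed=42)


@pytest.fixture(scope="session")
def tiny_injected_session():
    """Tiny session with four fixed injected excursions."""
    cfg = ad.SimulatorConfig()
    cfg.schedule.blocks = cfg.schedule.blocks[:2]
    cfg.tuning.n_units = 8
    cfg.excursions.mode = "fixed_count"
    cfg.excursions.n_fixed = 4
    return ad.make_session(cfg, seed=43)


@pytest.fixture(scope="session")
def tiny_coarse(tiny_session):
    return ad.build_ensemble(tiny_session, profile="coarse")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
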