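"""Shared fixtures: the packaged configuration and a fast miniature one."""

from dataclasses import replace

import numpy as np
import pytest

from eplabsim.input_model import Horizon, default_config


@pytest.fixture(scope="session")
def cfg():
    """The packaged department configuration (session-wide, read-only)."""
    return default_config()


@pytest.fixture(scope="session")
def small_cfg(cfg):
    """Same department, short horizon: cheap enough for many replications."""
    return replace(cfg, horizon=Horizon(warmup_days=5, observation_days=15,
                                        replications=50))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
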