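"""Shared fixtures.

The expensive scenario runs used by the acceptance tests are session-scoped
so that several criteria can be checked against the same simulations, exactly
as the corresponding summary statistics are pooled in practice.
"""

from __future__ import annotations

import numpy as np
import pytest

import ibsem
from ibsem.engine import run_scenario, scenario_preset

DESK_SCALE = 1 / 25


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def profile():
    return ibsem.make_effect_profile()


@pytest.fixture(scope="session")
def cfg():
    return ibsem.default_config()


@pytest.fixture(scope="session")
def scenario1(cfg):
    """Wild-population equilibrium run: 100 y settle + 100 y monitoring,
    3 replicates at 1/25 river scale."""
    spec = scenario_preset(1, replicates=3, scale=DESK_SCALE)
    return run_scenario(spec, cfg, master_seed=20)


@pytest.fixture(scope="session")
def scenario2(cfg):
    """Farm-initialized population evolving for 200 years (3 replicates)."""
    spec = scenario_preset(2, replicates=3, scale=DESK_SCALE)
    return run_scenario(spec, cfg, master_seed=21)


@pytest.fixture(scope="session")
def scenarios345(cfg):
    """High-introgression sensitivity runs at x1 / x0.5 / x2 differentials."""
    out = {}
    for sid in (3, 4, 5):
        spec = scenario_preset(sid, introgression="high", replicates=1,
                               scale=DESK_SCALE)
        out[sid] = run_scenario(spec, cfg, master_seed=22)
    return out
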