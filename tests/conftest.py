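"""Shared session fixtures: the default walker, optimized parameters and a
limit-cycle snapshot at 0.97 m/s (the speed most trial-based tests use)."""

import pytest

from reflexwalk.disturbances import make_snapshot
from reflexwalk.fixtures import fixture_params
from reflexwalk.walker import ReflexWalker


@pytest.fixture(scope="session")
def walker():
    return ReflexWalker(height=1.8, mass=80.0)


@pytest.fixture(scope="session")
def params097():
    return fixture_params(0.97)


@pytest.fixture(scope="session")
def snap097(walker, params097):
    return make_snapshot(walker, params097, v0=0.97)
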