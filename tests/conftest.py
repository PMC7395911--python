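from dataclasses import replace

import pytest

from edsim import engine, fixtures


@pytest.fixture(scope="session")
def fixture_graph():
    return fixtures.build_fixture_graph(fixtures.FixtureSpec())


@pytest.fixture(scope="session")
def fixture_config():
    return fixtures.build_fixture_config(fixtures.FixtureSpec())


@pytest.fixture(scope="session")
def small_run(fixture_graph, fixture_config):
    """One short realistic run shared by read-only tests."""
    arrivals, staffing, policy, sim = fixture_config
    sim = replace(sim, horizon_days=3, seed=11)
    return engine.run(fixture_graph, arrivals, staffing, policy, sim)
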