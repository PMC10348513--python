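import datetime as dt

import pytest

from divehab.simulate import SimConfig, gen_environment, gen_tracks_and_dives

COLONY = (-54.18, 46.81)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_birds=2,
        date_range=(dt.date(2021, 7, 15), dt.date(2021, 7, 24)),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_env(small_config):
    return gen_environment(small_config)


@pytest.fixture(scope="session")
def small_world(small_config, small_env):
    """(config, env, fixes, traces, truth) for a 2-bird, 10-day simulation."""
    fixes, traces, truth = gen_tracks_and_dives(small_config, small_env)
    return small_config, small_env, fixes, traces, truth
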