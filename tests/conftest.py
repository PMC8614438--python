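import datetime as dt

import pytest

import felimove as fm


@pytest.fixture(scope="session")
def week_config() -> fm.SimConfig:
    """One animal, one week: the cheap workhorse dataset."""
    return fm.SimConfig(
        seed=7,
        n_animals=1,
        start_date=dt.date(2020, 11, 1),
        end_date=dt.date(2020, 11, 8),
    )


@pytest.fixture(scope="session")
def week_path(week_config):
    return fm.simulate_track(week_config, 0)


@pytest.fixture(scope="session")
def week_fixes(week_config, week_path):
    return fm.sample_gps(week_path, week_config)


@pytest.fixture(scope="session")
def week_bursts(week_config, week_path):
    return fm.simulate_acc(week_path, week_config)


@pytest.fixture(scope="session")
def week_series(week_bursts):
    return fm.series_from_bursts(week_bursts)
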