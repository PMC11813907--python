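import datetime as dt

import numpy as np
import pytest

import fruitcast as fc


@pytest.fixture()
def const20_series():
    """60 days of constant 20 degC starting 2022-09-01."""
    days = np.arange(np.datetime64("2022-09-01"), np.datetime64("2022-10-31"))
    return fc.TemperatureSeries(days=days, temps=np.full(days.size, 20.0))


@pytest.fixture()
def const20_clock(const20_series):
    return fc.ThermalClock(dt.date(2022, 9, 1), const20_series)


@pytest.fixture()
def varied_clock():
    """Daily means [18, 22, 20, 14, 18, 22, 26] from 2022-09-01."""
    series = fc.TemperatureSeries(
        days=np.arange(np.datetime64("2022-09-01"), np.datetime64("2022-09-08")),
        temps=np.array([18.0, 22.0, 20.0, 14.0, 18.0, 22.0, 26.0]),
    )
    return fc.ThermalClock(dt.date(2022, 9, 1), series)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest three-cultivar simulated experiment shared across tests."""
    cfg = fc.default_config(seed=11, n_fruits=60)
    series, fruits, calibration = fc.simulate_cohort(cfg)
    return cfg, series, fruits, calibration
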