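import dataclasses

import numpy as np
import pandas as pd
import pytest

from chronolfp import BandPowerSeries, DiurnalSimConfig


def make_series(values, start="2021-06-01", interval_min=10, tz="UTC", **kw):
    """Series on a regular grid from a plain value array."""
    ts = pd.date_range(start, periods=len(values),
                       freq=pd.Timedelta(minutes=interval_min), tz=tz)
    return BandPowerSeries(ts, values,
                           sample_interval=pd.Timedelta(minutes=interval_min),
                           **kw)


@pytest.fixture
def step_config():
    """Noise-free two-level day/night configuration (day 4, night 2)."""
    return DiurnalSimConfig(n_days=4, day_level=4.0, night_level=2.0,
                            sleep_window=("00:00", "06:00"), noise_cv=0.0,
                            outlier_rate=0.0, transition_min=1.0, seed=0)


@pytest.fixture
def noisy_config(step_config):
    """30-day noisy variant of the two-level configuration."""
    return dataclasses.replace(step_config, n_days=30, noise_cv=0.2,
                               transition_min=30.0, seed=1)


@pytest.fixture
def flat_config(step_config):
    """No diurnal structure: equal day and night levels, noise only."""
    return dataclasses.replace(step_config, n_days=30, night_level=4.0,
                               noise_cv=0.3, transition_min=1.0, seed=2)


def mc_standard_error(samples):
    samples = np.asarray(samples, dtype=float)
    return samples.std(ddof=1) / np.sqrt(samples.size)
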