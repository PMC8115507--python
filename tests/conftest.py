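import numpy as np
import pandas as pd
import pytest

from pondwi.bucket import BucketParams
from pondwi.domain import make_domain
from pondwi.forcing import IrrigationSchedule, make_forcing
from pondwi.pipeline import PipelineConfig, simulate_scenarios

YEAR_DATES = pd.date_range("2018-01-01", "2018-12-31", freq="D")


@pytest.fixture(scope="session")
def year_dates():
    return YEAR_DATES


@pytest.fixture(scope="session")
def small_domain():
    return make_domain(24, 20, seed=7, farm_fraction=0.3)


@pytest.fixture(scope="session")
def forcing(year_dates):
    return make_forcing(year_dates, seed=3)


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(n_rows=24, n_cols=20, seed=11,
                          calib_n_bootstrap=50)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """Baseline + irrigation scenario cubes on a 24x20 domain."""
    return simulate_scenarios(small_config)


@pytest.fixture()
def idle_params():
    """Bucket parameters with all losses, jitter and baseflow disabled."""
    return BucketParams(
        drainage_coeff={0: 0.0, 1: 0.0, 2: 0.0},
        et_coeff=0.0, slope_drainage_gain=0.0, riparian_floor=0.0,
        initial_saturation=0.0, capacity_jitter=0.0, drainage_jitter=0.0,
        channel_return=0.0)


@pytest.fixture()
def off_schedule():
    return IrrigationSchedule(enabled=False)


def random_saturation_cube(rng, n_days=60, n_rows=6, n_cols=5):
    from pondwi.cubes import SaturationCube
    values = rng.random((n_days, n_rows, n_cols))
    dates = YEAR_DATES[:n_days]
    return SaturationCube(values=values, dates=dates)
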