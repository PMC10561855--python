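import datetime

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from forestnep.core import ForestType, WeatherDay, species_defaults


@pytest.fixture
def ecf_params():
    return species_defaults(ForestType.ECF)


@pytest.fixture
def ebf_params():
    return species_defaults(ForestType.EBF)


def make_day(
    date=datetime.date(2001, 6, 1),
    T_max=25.0, T_min=15.0, T_avg=20.0,
    precip=0.0, D=12.0, Rh=0.7,
    C_t=380.0, C_0=380.0, T_d=None, T_n=None, PAR_noon=400.0,
) -> WeatherDay:
    """Hand-built forcing day with derived fields pre-filled."""
    d = WeatherDay(date=date, T_max=T_max, T_min=T_min, T_avg=T_avg,
                   precip=precip, D=D, Rh=Rh, C_t=C_t, C_0=C_0)
    d.T_d = T_d if T_d is not None else T_avg + 0.5 * (T_max - T_avg)
    if T_n is not None:
        d.T_n = T_n
    elif D >= 24.0:
        d.T_n = T_avg
    else:
        d.T_n = (24.0 * T_avg - D * d.T_d) / (24.0 - D)
    d.PAR_noon = PAR_noon
    return d


@pytest.fixture
def constant_year():
    """One 365-day year of identical mild forcing (2001 is not a leap year)."""
    start = datetime.date(2001, 1, 1)
    return [
        make_day(date=start + datetime.timedelta(days=i))
        for i in range(365)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
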