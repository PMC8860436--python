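import datetime as dt

import pytest

from ssims.environment import ClimatologyParams, synthesize_season

SEASON_START = dt.date(2021, 3, 1)
SEASON_END = dt.date(2021, 9, 1)


@pytest.fixture(scope="session")
def mean_curve_temps():
    """The climatological mean season (noise-free envelope).

    Season-level qualitative properties are checked against the seasonal
    envelope rather than a particular noise realization, whose July can be
    atypically cool or warm.
    """
    return synthesize_season(
        ClimatologyParams(noise_sd=0.0), SEASON_START, SEASON_END, seed=0
    )


@pytest.fixture(scope="session")
def noisy_temps():
    """One seeded realization with daily AR(1) noise."""
    return synthesize_season(ClimatologyParams(), SEASON_START, SEASON_END, seed=11)
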