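"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rainlag import synthetic
from rainlag.datamodel import TrapEvent


@pytest.fixture(scope="session")
def default_lag_matrix():
    """Thinned lag matrix under the default planted-effect scenario (seed 1)."""
    cfg = synthetic.SyntheticConfig(seed=1, n_days=140, n_stations=40, n_traps=500)
    return synthetic.gen_lag_matrix(cfg)


@pytest.fixture(scope="session")
def null_lag_matrix():
    """Lag matrix with no planted precipitation effects (presence is noise)."""
    zero = np.zeros(20)
    cfg = synthetic.SyntheticConfig(seed=7, n_days=140, n_stations=40, n_traps=300,
                                    lag_effects_presence=zero,
                                    lag_effects_abundance=zero)
    return synthetic.gen_lag_matrix(cfg)


def make_effort_events(year: int, trap_type: str, n_traps: int, n_surveys: int,
                       n_nonzero: int, n_female_positive: int,
                       total_mosquitoes: int, total_females: int) -> list[TrapEvent]:
    """Construct a trap-event list realizing exact published effort totals.

    Counts are distributed so that group sums hit the requested integers
    exactly: the first female-positive event absorbs the female surplus, the
    first male-only event (or the first event) absorbs the male surplus, and
    every other nonzero event holds a single mosquito.
    """
    total_males = total_mosquitoes - total_females
    n_male_only = n_nonzero - n_female_positive
    assert 0 <= n_female_positive <= n_nonzero <= n_surveys
    assert total_females >= n_female_positive
    assert total_males >= n_male_only

    females = [0] * n_surveys
    males = [0] * n_surveys
    for i in range(n_female_positive):
        females[i] = 1
    if n_female_positive:
        females[0] += total_females - n_female_positive
    for i in range(n_female_positive, n_nonzero):
        males[i] = 1
    spare_males = total_males - n_male_only
    if n_male_only:
        males[n_female_positive] += spare_males
    elif n_surveys:
        males[0] += spare_males

    date = dt.date(year, 6, 1)
    return [TrapEvent(trap_id=f"{trap_type}{year}_{i % n_traps:04d}",
                      lon=-112.0 + (i % 50) * 1e-3, lat=33.3 + (i // 50) * 1e-4,
                      trap_type=trap_type, collection_date=date,
                      female_count=females[i], male_count=males[i])
            for i in range(n_surveys)]


@pytest.fixture(scope="session")
def published_effort_events():
    """Event set whose group totals equal the published 2014-2016 effort table."""
    events = []
    events += make_effort_events(2014, "CO2", 666, 28131, 3951, 3751, 39915, 27208)
    events += make_effort_events(2015, "CO2", 785, 34447, 6051, 5951, 37746, 24155)
    events += make_effort_events(2016, "CO2", 794, 37901, 6560, 6075, 44219, 32132)
    events += make_effort_events(2016, "BG", 19, 278, 105, 105, 377, 254)
    return events
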