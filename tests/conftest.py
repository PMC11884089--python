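import datetime as dt

import numpy as np
import pytest

from relacc import EpochSeries

WEEKDAY = dt.date(2024, 3, 4)   # Monday
SATURDAY = dt.date(2024, 3, 9)
SUNDAY = dt.date(2024, 3, 10)


def make_series(
    enmo,
    epoch_seconds: int = 5,
    date: dt.date = WEEKDAY,
    wear=None,
    participant_id: str = "T001",
):
    """EpochSeries from raw values; scalars are broadcast over the day."""
    n = 86400 // epoch_seconds
    enmo = np.asarray(enmo, dtype=float)
    if enmo.ndim == 0:
        enmo = np.full(n, float(enmo))
    if wear is None:
        wear = np.ones(n, dtype=bool)
    return EpochSeries(
        participant_id=participant_id,
        date=date,
        epoch_seconds=epoch_seconds,
        enmo=enmo,
        wear=np.asarray(wear, dtype=bool),
    )


@pytest.fixture
def series_factory():
    return make_series


def week_dates():
    """Mon..Sun of one calendar week (5 weekdays + Saturday + Sunday)."""
    return [WEEKDAY + dt.timedelta(days=j) for j in range(7)]
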