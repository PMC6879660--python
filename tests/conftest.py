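from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from acmkit.timeseries import ChannelSeries

START = datetime(2019, 11, 25, 0, 0)  # a Monday


def make_series(
    values,
    variable: str = "A",
    valid=None,
    start: datetime = START,
    epoch_minutes: int = 10,
    units: str = "",
) -> ChannelSeries:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    return ChannelSeries(
        variable=variable,
        start=start,
        epoch_minutes=epoch_minutes,
        values=values,
        valid=np.asarray(valid, dtype=bool),
        units=units,
    )


@pytest.fixture
def monday():
    return START
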