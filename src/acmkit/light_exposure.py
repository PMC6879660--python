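"""Time-in-bin analysis of raw light exposure by daytime interval.

Each valid 10-min epoch of the raw-lux channel contributes its 10 minutes to
exactly one cell of a 3 x 4 table: daytime interval {night 00:00-07:50,
morning 08:00-15:50, evening 16:00-23:50} x intensity bin {<10 lux (very low),
10-100 (low), 100-1000 (indoor bright), >1000 (outdoor bright)}.  Interval
labels follow the epoch-start convention, so "08:00 to 15:50" means the 48
epochs covering 08:00:00-16:00:00 and the three intervals tile the day.  Bin
edges are half-open, lower-inclusive: [0,10), [10,100), [100,1000), [1000,inf).
Cells are averaged over recording days and reported in minutes/day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import ChannelSeries

INTERVALS = ("night", "morning", "evening")  # in slot order 00:00 / 08:00 / 16:00
BIN_LABELS = ("<10 lux", "10-100 lux", "100-1000 lux", ">1000 lux")
BIN_EDGES = (0.0, 10.0, 100.0, 1000.0, np.inf)


@dataclass
class LightExposureTable:
    """Per-subject light time-in-bin result.

    ``minutes_per_day`` is a 3 x 4 array (interval x bin) of mean minutes/day;
    ``per_day`` keeps the underlying (n_days, 3, 4) counts in minutes, and
    ``valid_minutes_per_day`` the valid-epoch minutes per (day, interval) for
    conservation checks.
    """

    subject_id: str
    minutes_per_day: np.ndarray
    per_day: np.ndarray
    valid_minutes_per_day: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.minutes_per_day, index=list(INTERVALS), columns=list(BIN_LABELS)
        )


def _format_hmm(minutes: float) -> str:
    m = int(round(minutes))
    return f"{m // 60}:{m % 60:02d}"


def time_in_bins(light: ChannelSeries, subject_id: str = "") -> LightExposureTable:
    """Tabulate minutes/day spent in each (daytime interval, lux bin) cell.

    Requires the raw-lux channel (a cleaned week whose maximum valid value is
    below 10 is rejected as almost certainly log-transformed input).
    """
    if light.variable != "L":
        raise ValueError("time-in-bin analysis applies to the light channel")
    vals = light.valid_values()
    if vals.size == 0:
        raise ValueError("no valid light epochs")
    if (vals < 0).any():
        raise ValueError("negative lux values present")
    if vals.max() < 10.0:
        raise ValueError(
            "light channel looks log-transformed (max < 10 lux); pass raw lux"
        )
    p = light.slots_per_day
    slots = light.slot_of_day()
    day_idx = np.arange(light.n_epochs) // p
    n_days = int(day_idx[-1]) + 1
    interval_idx = slots * 3 // p  # 0 night, 1 morning, 2 evening
    bin_idx = np.digitize(light.values, BIN_EDGES[1:-1], right=False)

    per_day = np.zeros((n_days, 3, 4))
    valid_minutes = np.zeros((n_days, 3))
    m = light.valid & np.isfinite(light.values)
    np.add.at(per_day, (day_idx[m], interval_idx[m], bin_idx[m]), light.epoch_minutes)
    np.add.at(valid_minutes, (day_idx[m], interval_idx[m]), light.epoch_minutes)
    return LightExposureTable(
        subject_id=subject_id,
        minutes_per_day=per_day.mean(axis=0),
        per_day=per_day,
        valid_minutes_per_day=valid_minutes,
    )


def exposure_frame(tables: list[LightExposureTable], hmm: bool = False) -> pd.DataFrame:
    """Tidy cohort table: one row per subject x interval, bins as columns."""
    rows = []
    for t in tables:
        for i, interval in enumerate(INTERVALS):
            row: dict = {"subject_id": t.subject_id, "interval": interval}
            for j, lab in enumerate(BIN_LABELS):
                v = t.minutes_per_day[i, j]
                row[lab] = _format_hmm(v) if hmm else v
            rows.append(row)
    return pd.DataFrame(rows)
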