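"""Epoch-grid time series: the common representation for all recorded channels.

Raw logger streams arrive at heterogeneous rates (wrist temperature every
10 min, accelerometer-derived activity/position every 30 s, light and
environmental temperature at 10 min or faster).  Everything is resampled onto a
uniform 10-min grid anchored to the wall clock, with a parallel validity mask;
downstream statistics skip invalid epochs and never impute.

Epoch convention: half-open, left-labelled.  The epoch labelled 08:00 covers
[08:00:00, 08:10:00).  Days are calendar days in local clock time; no DST
handling (the intended recording windows contain none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

#: Recognised channel codes: wrist temperature, activity, position, light,
#: environmental temperature, the integrated TAP variable, and diary sleep.
VARIABLES = ("WT", "A", "P", "L", "ET", "TAP", "S")

DEFAULT_EPOCH_MINUTES = 10

#: Channels whose acrophase falls in the rest period (most-active window is
#: nocturnal): wrist temperature and sleep.  Everything else peaks by day.
NOCTURNAL_ACROPHASE = frozenset({"WT", "S"})


class GridMismatchError(ValueError):
    """Two channel series do not share the same epoch grid."""


@dataclass
class ChannelSeries:
    """One variable's uniform epoch series with a validity mask.

    Parameters
    ----------
    variable : str
        One of :data:`VARIABLES`.
    start : datetime
        Start of epoch 0 (local clock, naive).
    epoch_minutes : int
        Epoch length; 10 is canonical and must divide 1440.
    values : ndarray of float
    valid : ndarray of bool
        Parallel mask; invalid epochs are excluded from every statistic.
    units : str
    """

    variable: str
    start: datetime
    epoch_minutes: int
    values: np.ndarray
    valid: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if 1440 % self.epoch_minutes != 0:
            raise ValueError("epoch_minutes must divide 1440")
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or self.values.ndim != 1:
            raise ValueError("values and valid must be parallel 1-d arrays")

    # -- grid geometry -----------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return self.values.size

    @property
    def slots_per_day(self) -> int:
        return 1440 // self.epoch_minutes

    @property
    def n_days(self) -> float:
        return self.n_epochs / self.slots_per_day

    def epoch_starts(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=self.n_epochs, freq=f"{self.epoch_minutes}min"
        )

    def slot_of_day(self) -> np.ndarray:
        """Epoch-of-day slot index (0 = the epoch starting at 00:00)."""
        offset_min = (
            self.start.hour * 60 + self.start.minute + self.start.second / 60.0
        )
        first_slot = offset_min / self.epoch_minutes
        if abs(first_slot - round(first_slot)) > 1e-9:
            raise ValueError("series start is not aligned to the epoch grid")
        idx = (int(round(first_slot)) + np.arange(self.n_epochs)) % self.slots_per_day
        return idx

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def with_values(self, values: np.ndarray) -> "ChannelSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def with_mask(self, valid: np.ndarray) -> "ChannelSeries":
        return replace(self, valid=np.asarray(valid, dtype=bool))

    def same_grid(self, other: "ChannelSeries") -> bool:
        return (
            self.start == other.start
            and self.epoch_minutes == other.epoch_minutes
            and self.n_epochs == other.n_epochs
        )


@dataclass
class DailyWaveform:
    """Mean 24-h profile of one variable on the epoch-of-day grid.

    ``values[slot]`` is the mean of all valid epochs mapping to that
    epoch-of-day across days; ``n_contributing[slot]`` counts them.  Slots with
    zero contributions hold NaN and make the waveform incomplete.
    """

    variable: str
    values: np.ndarray
    n_contributing: np.ndarray
    epoch_minutes: int = DEFAULT_EPOCH_MINUTES
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        p = 1440 // self.epoch_minutes
        if self.values.size != p or self.n_contributing.size != p:
            raise ValueError(f"waveform must have exactly {p} slots")

    @property
    def slots(self) -> int:
        return self.values.size

    @property
    def complete(self) -> bool:
        return bool((self.n_contributing > 0).all())

    def slot_clock_hours(self) -> np.ndarray:
        """Clock time (hours) of each slot's epoch start."""
        return np.arange(self.slots) * self.epoch_minutes / 60.0


# ---------------------------------------------------------------------------
# resampling


def resample_to_grid(
    raw: pd.Series,
    variable: str,
    method: str,
    epoch_minutes: int = DEFAULT_EPOCH_MINUTES,
    units: str = "",
) -> ChannelSeries:
    """Resample a raw timestamped stream onto the uniform clock-anchored grid.

    Parameters
    ----------
    raw : pandas.Series
        Values indexed by naive local timestamps, time-sorted.
    variable : str
    method : {'mean', 'sum'}
        ``sum`` accumulates within each epoch (activity); ``mean`` averages
        (temperature, position, light).
    epoch_minutes : int
        Grid resolution; epochs are anchored to clock decades (hh:00, hh:10, …).

    The grid is anchored to the clock, not to the first sample.  Partial epochs
    at either end (raw coverage does not span the full epoch) are dropped.
    Interior epochs containing no raw samples are kept but marked invalid.

    Raises
    ------
    ValueError
        If the input is unsorted or contains duplicate timestamps; the message
        names the first offending timestamp.
    """
    if method not in ("mean", "sum"):
        raise ValueError(f"method must be 'mean' or 'sum', got {method!r}")
    if raw.empty:
        raise ValueError("empty raw stream")
    idx = pd.DatetimeIndex(raw.index)
    diffs = idx[1:] - idx[:-1]
    bad = np.flatnonzero(diffs <= pd.Timedelta(0))
    if bad.size:
        kind = "duplicate" if diffs[bad[0]] == pd.Timedelta(0) else "unsorted"
        raise ValueError(f"{kind} timestamp in raw stream at {idx[bad[0] + 1]}")

    step = pd.Timedelta(minutes=epoch_minutes)
    # sampling interval, for deciding whether the last epoch is fully covered
    dt = diffs.median() if len(diffs) else pd.Timedelta(0)
    coverage_start = idx[0]
    coverage_end = idx[-1] + dt

    first_epoch = idx[0].ceil(step) if idx[0] != idx[0].floor(step) else idx[0]
    n = int((coverage_end - first_epoch) // step)
    if n < 1:
        raise ValueError("raw stream does not cover a single full epoch")
    grid = pd.date_range(first_epoch, periods=n, freq=step)

    epoch_idx = ((idx - first_epoch) // step).astype(int)
    in_range = (epoch_idx >= 0) & (epoch_idx < n)
    vals = raw.to_numpy(dtype=float)[in_range]
    epoch_idx = epoch_idx[in_range]

    counts = np.bincount(epoch_idx, minlength=n)
    sums = np.bincount(epoch_idx, weights=vals, minlength=n)
    valid = counts > 0
    out = np.full(n, np.nan)
    if method == "sum":
        out[valid] = sums[valid]
    else:
        out[valid] = sums[valid] / counts[valid]
    return ChannelSeries(
        variable=variable,
        start=grid[0].to_pydatetime(),
        epoch_minutes=epoch_minutes,
        values=out,
        valid=valid,
        units=units,
    )


# ---------------------------------------------------------------------------
# waveform averaging

MIN_DAYS = 7


def mean_waveform(series: ChannelSeries, toy_mode: bool = False) -> DailyWaveform:
    """Per-subject mean 24-h waveform of one channel.

    Each valid epoch contributes to the epoch-of-day slot it starts in; the
    slot value is the mean across days.  Requires at least 7 complete days of
    grid coverage unless ``toy_mode`` relaxes the rule for small examples.
    """
    p = series.slots_per_day
    if not toy_mode and series.n_epochs < MIN_DAYS * p:
        raise ValueError(
            f"{series.variable}: {series.n_days:.2f} days recorded; "
            f"7 complete days required"
        )
    slots = series.slot_of_day()
    m = series.valid & np.isfinite(series.values)
    counts = np.bincount(slots[m], minlength=p)
    sums = np.bincount(slots[m], weights=series.values[m], minlength=p)
    sq = np.bincount(slots[m], weights=series.values[m] ** 2, minlength=p)
    values = np.full(p, np.nan)
    sem = np.full(p, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    two = counts > 1
    var = np.zeros(p)
    var[two] = (sq[two] - counts[two] * values[two] ** 2) / (counts[two] - 1)
    sem[two] = np.sqrt(np.maximum(var[two], 0.0) / counts[two])
    return DailyWaveform(
        variable=series.variable,
        values=values,
        n_contributing=counts,
        epoch_minutes=series.epoch_minutes,
        sem=sem,
    )


def group_waveform(waveforms: list[DailyWaveform]) -> DailyWaveform:
    """Slot-wise mean of per-subject waveforms (all the same variable).

    Slots missing for a subject are skipped for that subject; the returned
    ``sem`` is the between-subject standard error used for plotting bands.
    """
    if not waveforms:
        raise ValueError("empty waveform list")
    var = waveforms[0].variable
    p = waveforms[0].slots
    for w in waveforms:
        if w.variable != var or w.slots != p:
            raise ValueError("waveforms must share variable and grid")
    stack = np.vstack([w.values for w in waveforms])
    n = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(stack, axis=0), np.nan)
        sd = np.where(n > 1, np.nanstd(stack, axis=0, ddof=1), np.nan)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return DailyWaveform(
        variable=var,
        values=mean,
        n_contributing=n,
        epoch_minutes=waveforms[0].epoch_minutes,
        sem=sem,
    )


@dataclass
class SubjectRecording:
    """All channels, diary and metadata for one subject.

    ``channels`` maps variable code to :class:`ChannelSeries`; after
    resampling all channels share the epoch grid.  ``diary`` and ``site`` are
    filled by the diary and phase-marker layers.
    """

    subject_id: str
    channels: dict = field(default_factory=dict)
    diary: object | None = None
    site: object | None = None
    weekday_of_start: int = 0

    def analyzable(self, variable: str) -> bool:
        """Channel present and spanning at least 7 complete days."""
        ch = self.channels.get(variable)
        if ch is None:
            return False
        return ch.n_epochs >= MIN_DAYS * ch.slots_per_day
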