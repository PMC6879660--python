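"""Sleep diary: binary sleep series, sleep probability, MSFsc and social jetlag.

The diary records nocturnal sleep episodes, naps, and sensor-removal intervals.
Binary sleep (the S channel) marks an epoch asleep when its midpoint falls in
any declared sleep or nap interval.  Chronotype from the diary follows the
Munich ChronoType Questionnaire convention: midsleep on free days corrected for
weekly sleep debt (MSFsc), with the asymmetric day-class lists — onsets on
Sunday–Thursday count as work nights and Friday–Saturday as free, while offsets
on Monday–Friday are work and Saturday–Sunday free.  Social jetlag is the
absolute circular difference between work-day and free-day midsleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .circular import circ_dist, circ_mean, signed_diff, wrap_hours
from .timeseries import ChannelSeries, DailyWaveform, group_waveform, mean_waveform

Interval = tuple[datetime, datetime]

# weekday() numbers: Mon=0 … Sun=6
_ONSET_WORK = {6, 0, 1, 2, 3}   # Sunday–Thursday
_ONSET_FREE = {4, 5}            # Friday, Saturday
_OFFSET_WORK = {0, 1, 2, 3, 4}  # Monday–Friday
_OFFSET_FREE = {5, 6}           # Saturday, Sunday


class InsufficientDiaryError(ValueError):
    """Too few work or free nights to compute MSFsc; subject is excluded."""


@dataclass
class DiaryRecord:
    """Per-subject diary: nocturnal sleep episodes, naps, sensor removals."""

    subject_id: str
    sleep_intervals: list[Interval] = field(default_factory=list)
    nap_intervals: list[Interval] = field(default_factory=list)
    sensor_off_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("sleep_intervals", "nap_intervals", "sensor_off_intervals"):
            ivs = sorted(getattr(self, name))
            for a, b in ivs:
                if b <= a:
                    raise ValueError(f"{name}: end {b} not after start {a}")
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if a2 < b1:
                    raise ValueError(f"{name}: overlapping intervals at {a2}")
            setattr(self, name, ivs)


@dataclass(frozen=True)
class SleepTiming:
    """Weekly sleep timing summary (clock hours) and chronotype measures."""

    onset_work: float
    offset_work: float
    onset_free: float
    offset_free: float
    sd_work: float       # mean sleep duration, work nights (h)
    sd_free: float       # mean sleep duration, free nights (h)
    msw: float           # midsleep, work nights
    msf: float           # midsleep, free nights
    msfsc: float         # midsleep free, corrected for weekly sleep debt
    sjl: float           # social jetlag (h, >= 0)


def binarize_sleep(
    diary: DiaryRecord,
    start: datetime,
    n_epochs: int,
    epoch_minutes: int = 10,
    include_naps: bool = True,
) -> ChannelSeries:
    """Binary sleep series on the epoch grid from the diary.

    An epoch scores 1 when its midpoint m satisfies start < m <= end for any
    sleep (or nap) interval.  All epochs are valid: the diary is authoritative
    for sleep/wake.
    """
    mid = np.array(
        [
            start + timedelta(minutes=epoch_minutes * (i + 0.5))
            for i in range(n_epochs)
        ]
    )
    values = np.zeros(n_epochs)
    intervals = list(diary.sleep_intervals)
    if include_naps:
        intervals += list(diary.nap_intervals)
    for a, b in intervals:
        values[(mid > a) & (mid <= b)] = 1.0
    return ChannelSeries(
        variable="S",
        start=start,
        epoch_minutes=epoch_minutes,
        values=values,
        valid=np.ones(n_epochs, dtype=bool),
        units="binary",
    )


def sleep_probability(cohort: list[ChannelSeries], toy_mode: bool = False) -> DailyWaveform:
    """Percentage of subjects asleep at each epoch of day.

    Each subject's binary series is first averaged into an individual daily
    sleep-probability waveform; the cohort waveform is the slot-wise mean of
    those, expressed in percent.
    """
    if not cohort:
        raise ValueError("empty cohort")
    wfs = [mean_waveform(s, toy_mode=toy_mode) for s in cohort]
    g = group_waveform(wfs)
    g.values = g.values * 100.0
    if g.sem is not None:
        g.sem = g.sem * 100.0
    return g


def _episode_clock(ts: datetime) -> float:
    return wrap_hours(ts.hour + ts.minute / 60.0 + ts.second / 3600.0)


def msfsc(
    diary: DiaryRecord,
    min_work_nights: int = 3,
    min_free_nights: int = 1,
) -> SleepTiming:
    """Compute MSFsc and social jetlag from the diary's nocturnal episodes.

    Each episode's onset is classified by its onset calendar date (Sun–Thu
    work, Fri–Sat free) and its offset independently by the offset date
    (Mon–Fri work, Sat–Sun free).  Clock times are combined by circular means;
    durations are plain means per class.  Then, with SD the mean duration:

        MSW   = onset_w + SD_w/2
        MSF   = onset_f + SD_f/2
        SD_wk = (5·SD_w + 2·SD_f)/7
        MSFsc = MSF − (SD_f − SD_wk)/2   if SD_f > SD_w, else MSF

    Raises :class:`InsufficientDiaryError` below the night minimums.
    """
    onsets_w, onsets_f, offsets_w, offsets_f = [], [], [], []
    dur_w, dur_f = [], []
    for a, b in diary.sleep_intervals:
        dur = (b - a).total_seconds() / 3600.0
        if a.weekday() in _ONSET_WORK:
            onsets_w.append(_episode_clock(a))
            dur_w.append(dur)
        else:
            onsets_f.append(_episode_clock(a))
            dur_f.append(dur)
        if b.weekday() in _OFFSET_WORK:
            offsets_w.append(_episode_clock(b))
        else:
            offsets_f.append(_episode_clock(b))
    if (
        len(onsets_w) < min_work_nights
        or len(onsets_f) < min_free_nights
        or not offsets_w
        or not offsets_f
    ):
        raise InsufficientDiaryError(
            f"{diary.subject_id}: {len(onsets_w)} work / {len(onsets_f)} free "
            f"night onsets ({len(offsets_w)}/{len(offsets_f)} offsets); "
            f"need >= {min_work_nights}/{min_free_nights}"
        )
    onset_w = circ_mean(onsets_w)
    onset_f = circ_mean(onsets_f)
    offset_w = circ_mean(offsets_w)
    offset_f = circ_mean(offsets_f)
    sd_w = float(np.mean(dur_w))
    sd_f = float(np.mean(dur_f))
    msw = wrap_hours(onset_w + sd_w / 2.0)
    msf = wrap_hours(onset_f + sd_f / 2.0)
    sd_week = (5.0 * sd_w + 2.0 * sd_f) / 7.0
    if sd_f > sd_w:
        msfsc_val = wrap_hours(msf - (sd_f - sd_week) / 2.0)
    else:
        msfsc_val = msf
    return SleepTiming(
        onset_work=onset_w,
        offset_work=offset_w,
        onset_free=onset_f,
        offset_free=offset_f,
        sd_work=sd_w,
        sd_free=sd_f,
        msw=msw,
        msf=msf,
        msfsc=msfsc_val,
        sjl=social_jetlag(msw, msf),
    )


def social_jetlag(msw: float, msf: float) -> float:
    """|circular difference| between work and free midsleep, hours in [0, 12]."""
    return circ_dist(msf, msw)
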