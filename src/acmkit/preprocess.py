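"""Channel cleaning: sensor-off masking, rate-of-change outlier removal, lux log.

Cleaning only ever touches the validity mask, never the stored values, and is
applied in a fixed order: diary-reported sensor removals are masked first, the
interquartile-distance (IQD) rate-of-change filter runs second, and the light
log transform is applied last (index computations on light use the transformed
series; the time-in-bin analysis always uses raw lux).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .timeseries import ChannelSeries


@dataclass(frozen=True)
class MaskInterval:
    """A clock interval to invalidate, e.g. a diary-reported sensor removal."""

    start: datetime
    end: datetime
    reason: str = "sensor_off"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must be after start")


def mask_intervals(
    series: ChannelSeries, intervals: list[MaskInterval]
) -> ChannelSeries:
    """Invalidate every epoch overlapping any interval (values untouched).

    Overlap uses the half-open epoch convention: epoch [t, t+10min) overlaps
    interval [a, b) iff t < b and a < t+10min.
    """
    if not intervals:
        return series.with_mask(series.valid.copy())
    starts = series.epoch_starts()
    step = timedelta(minutes=series.epoch_minutes)
    mask = series.valid.copy()
    for iv in intervals:
        hit = (starts < iv.end) & (starts + step > iv.start)
        mask[np.asarray(hit)] = False
    return series.with_mask(mask)


def iqd_outlier_filter(
    series: ChannelSeries, mode: str = "values", toy_mode: bool = False
) -> ChannelSeries:
    """Remove epochs whose rate of change from the previous value exceeds the IQD.

    The threshold is the interquartile distance Q3 − Q1 (linear-interpolation
    quartiles) of the valid values' distribution (``mode='values'``, default)
    or of the consecutive absolute differences (``mode='diffs'``).  In a single
    pass, d_i = |x_i − x_{i−1}| is computed over consecutive valid epochs of
    the input (previously masked gaps are bridged) and epoch i is invalidated
    when d_i > IQD.  Comparisons always use the input series, never the
    filter's own output: a stateful "last surviving value" variant would
    cascade after one genuine day–night level shift and discard whole nights.
    An isolated spike therefore costs two epochs (the spike and the return to
    baseline), which is the worst case for a transient artifact.

    A constant series (IQD = 0) removes nothing and emits a warning.
    """
    if mode not in ("values", "diffs"):
        raise ValueError(f"unknown IQD mode {mode!r}")
    vals = series.valid_values()
    if not toy_mode and vals.size < 8:
        raise ValueError("IQD filter needs at least 8 valid epochs")
    if mode == "values":
        q1, q3 = np.percentile(vals, [25, 75])
    else:
        d = np.abs(np.diff(vals))
        if d.size == 0:
            return series.with_mask(series.valid.copy())
        q1, q3 = np.percentile(d, [25, 75])
    iqd = float(q3 - q1)
    if iqd <= 0.0:
        warnings.warn(
            f"{series.variable}: IQD is zero (constant channel); no epochs removed",
            stacklevel=2,
        )
        return series.with_mask(series.valid.copy())

    mask = series.valid & np.isfinite(series.values)
    vidx = np.flatnonzero(mask)
    x = series.values[vidx]
    d = np.abs(np.diff(x))
    mask[vidx[1:][d > iqd]] = False
    return series.with_mask(mask)


def log_transform_light(series: ChannelSeries) -> ChannelSeries:
    """Convert lux to logarithmic units via log10(lux + 1).

    The +1 offset keeps 0 lux finite (and maps it to exactly 0).  Raises on a
    non-light channel or any negative valid lux value.
    """
    if series.variable != "L":
        raise ValueError("log transform applies to the light channel only")
    v = series.valid_values()
    if v.size and (v < 0).any():
        raise ValueError("negative lux values present")
    out = series.with_values(np.log10(np.clip(series.values, 0.0, None) + 1.0))
    out.units = "log10(lux)"
    return out
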