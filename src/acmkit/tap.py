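"""The integrated TAP variable: wrist Temperature (inverted), Activity, Position.

Each of the three cleaned channels is affinely normalized to [0, 1] using
per-subject robust bounds (5th/95th percentile of the cleaned week by default,
clamped outside), the wrist-temperature component is inverted (high WT is
sleep-like), and the three are averaged epoch-wise.  TAP = 0 is thus a
rest-like epoch (lowest activity, horizontal, warmest wrist) and TAP = 1 a
fully active one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import ChannelSeries, GridMismatchError


@dataclass(frozen=True)
class NormalizationSpec:
    """Affine [0, 1] normalization bounds for one channel.

    ``lo`` maps to 0 and ``hi`` to 1 (values outside are clamped); ``invert``
    flips the result and is used for wrist temperature only.
    """

    variable: str
    lo: float
    hi: float
    invert: bool = False

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(
                f"degenerate normalization for {self.variable}: lo == hi == {self.lo}"
            )


def percentile_spec(
    series: ChannelSeries,
    lower: float = 5.0,
    upper: float = 95.0,
) -> NormalizationSpec:
    """Per-subject normalization bounds from percentiles of the cleaned week."""
    vals = series.valid_values()
    if vals.size == 0:
        raise ValueError(f"{series.variable}: no valid epochs to normalize from")
    lo, hi = np.percentile(vals, [lower, upper])
    if not lo < hi:
        raise ValueError(
            f"degenerate normalization for {series.variable}: "
            f"p{lower:g} == p{upper:g} == {lo}"
        )
    return NormalizationSpec(
        variable=series.variable, lo=float(lo), hi=float(hi),
        invert=series.variable == "WT",
    )


def normalize_channel(series: ChannelSeries, spec: NormalizationSpec) -> ChannelSeries:
    """Map values through clamp((x − lo)/(hi − lo), 0, 1), then 1 − x if invert."""
    x = (series.values - spec.lo) / (spec.hi - spec.lo)
    x = np.clip(x, 0.0, 1.0)
    if spec.invert:
        x = 1.0 - x
    out = series.with_values(x)
    out.units = "normalized"
    return out


def integrate_tap(
    wt: ChannelSeries,
    a: ChannelSeries,
    p: ChannelSeries,
    min_components: int = 3,
) -> ChannelSeries:
    """Average the three normalized components into the TAP series.

    All three series must share the epoch grid and already be normalized to
    [0, 1] (WT inverted).  By default an epoch is valid only when all three
    components are valid; ``min_components=2`` enables the lenient extension
    that averages whatever is available when at least two components remain.
    """
    if min_components not in (2, 3):
        raise ValueError("min_components must be 2 or 3")
    if not (wt.same_grid(a) and wt.same_grid(p)):
        raise GridMismatchError("TAP components are not on the same epoch grid")
    comp = np.vstack([wt.values, a.values, p.values])
    ok = np.vstack([wt.valid, a.valid, p.valid]) & np.isfinite(comp)
    inside = (comp >= -1e-9) & (comp <= 1 + 1e-9)
    if (ok & ~inside).any():
        raise ValueError("TAP components must be normalized to [0, 1]")
    count = ok.sum(axis=0)
    valid = count >= min_components
    comp = np.where(ok, comp, 0.0)
    values = np.full(wt.n_epochs, np.nan)
    values[valid] = comp.sum(axis=0)[valid] / count[valid]
    values[valid] = np.clip(values[valid], 0.0, 1.0)
    out = ChannelSeries(
        variable="TAP",
        start=wt.start,
        epoch_minutes=wt.epoch_minutes,
        values=values,
        valid=valid,
        units="a.u.",
    )
    return out
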