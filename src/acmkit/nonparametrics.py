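"""Non-parametric circadian indexes: IS, IV, M/L levels, RA, NRA, CFI.

All indexes are computed on the canonical 10-min grid (144 epochs of day).
Interdaily stability (IS) is the ratio of the variance of the mean 24-h
pattern to the total variance — 1 for perfectly repeated days, near 0 for
noise.  Intradaily variability (IV) is the normalized mean-square successive
difference — near 0 for a smooth sinusoid, about 2 for white noise.  The most-
and least-active window levels (M10/L5, or M5/L10 for variables peaking at
night) give the relative amplitude RA = (M − L)/(M + L); RA is rescaled across
the cohort with a 5 %/95 % recoding to give NRA, which replaces RA in the
circadian function index CFI = (IS + (1 − IV/2) + NRA)/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .circular import wrap_hours
from .timeseries import ChannelSeries, DailyWaveform, NOCTURNAL_ACROPHASE


def window_hours(variable: str) -> tuple[int, int]:
    """(M_hours, L_hours) for a variable.

    Wrist temperature and sleep peak during the rest period, so their
    most-active window is the 5-h nocturnal one (M5/L10); every other channel
    uses M10/L5.
    """
    if variable in NOCTURNAL_ACROPHASE:
        return 5, 10
    return 10, 5


def _check_series(series: ChannelSeries, toy_mode: bool) -> np.ndarray:
    m = series.valid & np.isfinite(series.values)
    if not toy_mode:
        if series.n_epochs < 7 * series.slots_per_day:
            raise ValueError(f"{series.variable}: fewer than 7 days of data")
        if m.sum() < 0.8 * series.n_epochs:
            raise ValueError(f"{series.variable}: fewer than 80% valid epochs")
    return m


def interdaily_stability(series: ChannelSeries, toy_mode: bool = False) -> float:
    """IS = [N·Σ_h (x̄_h − x̄)²] / [p·Σ_i (x_i − x̄)²], clamped to [0, 1].

    h runs over the p epoch-of-day slots (hourly means of the slots are not
    used: the index is computed at full 10-min resolution), i over all N valid
    epochs.  Raises on zero total variance.
    """
    m = _check_series(series, toy_mode)
    x = series.values[m]
    n = x.size
    xbar = x.mean()
    total = ((x - xbar) ** 2).sum()
    if total <= 0:
        raise ValueError(f"{series.variable}: zero variance, IS undefined")
    p = series.slots_per_day
    slots = series.slot_of_day()[m]
    counts = np.bincount(slots, minlength=p)
    sums = np.bincount(slots, weights=x, minlength=p)
    nz = counts > 0
    slot_means = sums[nz] / counts[nz]
    between = ((slot_means - xbar) ** 2).sum()
    return float(np.clip((n * between) / (p * total), 0.0, 1.0))


def intradaily_variability(series: ChannelSeries, toy_mode: bool = False) -> float:
    """IV = [N·Σ (x_i − x_{i−1})²] / [m·Σ (x_i − x̄)²] over consecutive valid pairs.

    m is the number of grid-adjacent pairs with both epochs valid (equal to
    N − 1 on gap-free data).  Raises on zero variance or no adjacent pairs.
    """
    msk = _check_series(series, toy_mode)
    x = series.values
    pair = msk[1:] & msk[:-1]
    n_pairs = int(pair.sum())
    if n_pairs == 0:
        raise ValueError(f"{series.variable}: no consecutive valid pairs")
    xs = x[np.flatnonzero(msk)]
    n = xs.size
    xbar = xs.mean()
    total = ((xs - xbar) ** 2).sum()
    if total <= 0:
        raise ValueError(f"{series.variable}: zero variance, IV undefined")
    diffs = (x[1:] - x[:-1])[pair]
    return float((n * (diffs**2).sum()) / (n_pairs * total))


@dataclass(frozen=True)
class MLResult:
    """Most- and least-active window levels and onsets of a daily waveform.

    Levels carry the variable's units; onsets are the starting epoch-of-day
    slots of the windows.  ``m_hours``/``l_hours`` record the window lengths
    used (10/5 for day-peaking variables, 5/10 for WT and sleep).
    """

    variable: str
    m_level: float
    m_onset_slot: int
    m_hours: int
    l_level: float
    l_onset_slot: int
    l_hours: int
    epoch_minutes: int = 10

    def _slot_hours(self, slot: int) -> float:
        return wrap_hours(slot * self.epoch_minutes / 60.0)

    @property
    def m_onset_hours(self) -> float:
        return self._slot_hours(self.m_onset_slot)

    @property
    def l_onset_hours(self) -> float:
        return self._slot_hours(self.l_onset_slot)

    @property
    def m_midpoint_hours(self) -> float:
        return wrap_hours(self.m_onset_hours + self.m_hours / 2.0)

    @property
    def l_midpoint_hours(self) -> float:
        return wrap_hours(self.l_onset_hours + self.l_hours / 2.0)


def ml_levels(
    waveform: DailyWaveform,
    m_hours: int | None = None,
    l_hours: int | None = None,
) -> MLResult:
    """Exhaustive circular search for the M and L windows of a daily waveform.

    Every one of the 144 window start slots is scanned (windows wrap across
    midnight); M is the maximum mean over ``m_hours`` consecutive hours, L the
    minimum over ``l_hours``.  Ties are broken by the earliest onset in
    epoch-of-day order starting at 00:00.  Raises on an incomplete waveform.
    """
    if m_hours is None or l_hours is None:
        mh, lh = window_hours(waveform.variable)
        m_hours = m_hours if m_hours is not None else mh
        l_hours = l_hours if l_hours is not None else lh
    if not waveform.complete:
        raise ValueError(f"{waveform.variable}: incomplete waveform (empty slots)")
    p = waveform.slots
    per_hour = 60 // waveform.epoch_minutes

    def window_means(width_slots: int) -> np.ndarray:
        doubled = np.concatenate([waveform.values, waveform.values])
        cs = np.concatenate([[0.0], np.cumsum(doubled)])
        return (cs[width_slots : width_slots + p] - cs[:p]) / width_slots

    m_means = window_means(m_hours * per_hour)
    l_means = window_means(l_hours * per_hour)
    m_onset = int(np.argmax(m_means))  # argmax/argmin return the first maximizer
    l_onset = int(np.argmin(l_means))
    return MLResult(
        variable=waveform.variable,
        m_level=float(m_means[m_onset]),
        m_onset_slot=m_onset,
        m_hours=int(m_hours),
        l_level=float(l_means[l_onset]),
        l_onset_slot=l_onset,
        l_hours=int(l_hours),
        epoch_minutes=waveform.epoch_minutes,
    )


def relative_amplitude(m_level: float, l_level: float) -> float:
    """RA = (M − L) / (M + L); requires M ≥ L and M + L > 0."""
    if m_level < l_level:
        raise ValueError("M level below L level")
    if m_level + l_level <= 0:
        raise ValueError("M + L must be positive for relative amplitude")
    return (m_level - l_level) / (m_level + l_level)


def normalize_ra_cohort(ra_values: np.ndarray) -> np.ndarray:
    """Rescale a cohort's RA values: top/bottom 5 % recoded to 1/0, rest affine.

    p5 and p95 are linear-interpolation percentiles of the cohort distribution
    (computed per variable).  Fewer than 20 subjects gives a warning; p5 == p95
    raises.
    """
    ra = np.asarray(ra_values, dtype=float)
    if ra.size < 20:
        warnings.warn(
            f"NRA rescaling on only {ra.size} subjects; percentiles are unstable",
            stacklevel=2,
        )
    p5, p95 = np.percentile(ra, [5, 95])
    if not p5 < p95:
        raise ValueError("degenerate cohort RA distribution (p5 == p95)")
    return np.clip((ra - p5) / (p95 - p5), 0.0, 1.0)


def circadian_function_index(IS: float, IV: float, NRA: float) -> float:
    """CFI = (IS + (1 − min(IV, 2)/2) + NRA) / 3, each component on [0, 1].

    IV is clamped at 2 (its white-noise value) so the fragmentation term stays
    in range.
    """
    if not (0.0 <= IS <= 1.0 and 0.0 <= NRA <= 1.0 and IV >= 0.0):
        raise ValueError("index inputs out of range")
    iv_term = 1.0 - min(IV, 2.0) / 2.0
    return (IS + iv_term + NRA) / 3.0
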