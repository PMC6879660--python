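"""Circular arithmetic on clock times.

Clock times are represented as hours in [0, 24) on a circle.  Naive averaging of
clock times fails around midnight (mean of 23:00 and 01:00 is not 12:00), so all
summaries of phase markers and sleep timing go through the helpers here.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np

HOURS_PER_DAY = 24.0


def parse_clock(text: str) -> float:
    """Parse ``'HH:MM'`` (optionally ``'HH:MM:SS'``) into hours in [0, 24)."""
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"not a clock time: {text!r}")
    h, m = int(parts[0]), int(parts[1])
    s = float(parts[2]) if len(parts) == 3 else 0.0
    if not (0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"not a clock time: {text!r}")
    return (h + m / 60.0 + s / 3600.0) % HOURS_PER_DAY


def format_clock(hours: float, seconds: bool = False) -> str:
    """Format hours on the 24-h circle as ``'HH:MM'`` (rounded to the minute)."""
    h = float(hours) % HOURS_PER_DAY
    if seconds:
        total = round(h * 3600)
        total %= 86400
        return f"{total // 3600:02d}:{(total % 3600) // 60:02d}:{total % 60:02d}"
    total_min = round(h * 60) % (24 * 60)
    return f"{total_min // 60:02d}:{total_min % 60:02d}"


def wrap_hours(hours: float) -> float:
    h = float(hours) % HOURS_PER_DAY
    # a tiny negative input can round to exactly 24.0 after the modulo
    return 0.0 if h >= HOURS_PER_DAY else h


def signed_diff(a: float, b: float) -> float:
    """Signed shortest difference a − b on the 24-h circle, in (−12, 12]."""
    d = (float(a) - float(b)) % HOURS_PER_DAY
    if d > 12.0:
        d -= HOURS_PER_DAY
    return d


def circ_dist(a: float, b: float) -> float:
    """Shortest distance between two clock times in hours, in [0, 12]."""
    return abs(signed_diff(a, b))


def circ_mean(times: Iterable[float]) -> float:
    """Circular mean of clock times (hours), in [0, 24).

    Undefined for an empty input or a perfectly balanced configuration
    (resultant length zero); both raise ``ValueError``.
    """
    arr = np.asarray(list(times), dtype=float)
    if arr.size == 0:
        raise ValueError("circular mean of empty sequence")
    ang = arr * (2.0 * math.pi / HOURS_PER_DAY)
    s, c = np.sin(ang).sum(), np.cos(ang).sum()
    if math.hypot(s, c) < 1e-12 * arr.size:
        raise ValueError("circular mean undefined: resultant length ~ 0")
    return wrap_hours(math.atan2(s, c) * HOURS_PER_DAY / (2.0 * math.pi))


def circ_sem(times: Iterable[float]) -> float:
    """Circular standard error of the mean, in hours.

    Uses the circular standard deviation sqrt(−2 ln R̄) divided by sqrt(n);
    adequate for the concentrated distributions seen in phase-marker summaries.
    """
    arr = np.asarray(list(times), dtype=float)
    n = arr.size
    if n < 2:
        return float("nan")
    ang = arr * (2.0 * math.pi / HOURS_PER_DAY)
    rbar = math.hypot(np.sin(ang).mean(), np.cos(ang).mean())
    rbar = min(max(rbar, 1e-12), 1.0)
    csd = math.sqrt(max(-2.0 * math.log(rbar), 0.0))
    return csd / math.sqrt(n) * HOURS_PER_DAY / (2.0 * math.pi)


def unwrap_about(times: Iterable[float], center: float | None = None) -> np.ndarray:
    """Map clock times onto a continuous axis centred on ``center``.

    Each time t becomes ``center + signed_diff(t, center)``; with the default
    (circular mean of the input) this places every value within ±12 h of the
    cohort's typical phase, so ordinary quantiles become meaningful for values
    straddling midnight.
    """
    arr = np.asarray(list(times), dtype=float)
    if center is None:
        center = circ_mean(arr)
    return center + np.array([signed_diff(t, center) for t in arr])
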