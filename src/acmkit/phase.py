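"""Circadian phase markers and the Circadian Health Index.

The night phase marker (NPM) of a variable is the timing of its nocturnal 5-h
window — L5 for day-peaking variables, M5 for wrist temperature and sleep —
and the day phase marker (DPM) the timing of the complementary 10-h window.
Timing is reported as the window midpoint by default (onset available via the
marker convention setting).

DM-NPM measures synchronization to the natural light–dark cycle: the shortest
circular distance (hours) between the NPM and the centre of natural darkness,
divided by the maximum possible 12 h.  The Circadian Health Index combines
amplitude, stability and synchronization:

    CHI = (NRA + IS + (1 − DM-NPM)) / 3
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .circular import circ_dist, parse_clock, wrap_hours
from .nonparametrics import MLResult
from .timeseries import NOCTURNAL_ACROPHASE

#: Default site solar times: midpoints of the late-autumn ranges at the
#: reference site (sunrise 07:56–08:18, sunset 17:45–17:50).
DEFAULT_SUNRISE = "08:07"
DEFAULT_SUNSET = "17:47"


def darkness_center(sunset: float | str, sunrise: float | str) -> float:
    """Circular midpoint of the night span sunset → next sunrise, in hours."""
    ss = parse_clock(sunset) if isinstance(sunset, str) else float(sunset)
    sr = parse_clock(sunrise) if isinstance(sunrise, str) else float(sunrise)
    if wrap_hours(ss) == wrap_hours(sr):
        raise ValueError("sunset and sunrise coincide")
    night = (sr - ss) % 24.0
    return wrap_hours(ss + night / 2.0)


@dataclass(frozen=True)
class SolarContext:
    """Site sunrise/sunset clock times and the derived darkness centre."""

    sunrise: float = field(default_factory=lambda: parse_clock(DEFAULT_SUNRISE))
    sunset: float = field(default_factory=lambda: parse_clock(DEFAULT_SUNSET))

    @classmethod
    def from_strings(cls, sunrise: str = DEFAULT_SUNRISE,
                     sunset: str = DEFAULT_SUNSET) -> "SolarContext":
        return cls(sunrise=parse_clock(sunrise), sunset=parse_clock(sunset))

    @property
    def darkness_center(self) -> float:
        return darkness_center(self.sunset, self.sunrise)


def _marker(ml: MLResult, hours: int, convention: str) -> float:
    nocturnal = ml.variable in NOCTURNAL_ACROPHASE
    # the nocturnal window is M for WT/S, L for everything else
    use_m = (nocturnal and hours == 5) or (not nocturnal and hours == 10)
    have = ml.m_hours if use_m else ml.l_hours
    if have != hours:
        raise ValueError(
            f"{ml.variable}: window of {have} h cannot provide a {hours}-h marker"
        )
    if convention == "midpoint":
        return ml.m_midpoint_hours if use_m else ml.l_midpoint_hours
    if convention == "onset":
        return ml.m_onset_hours if use_m else ml.l_onset_hours
    raise ValueError(f"unknown marker convention {convention!r}")


def night_phase_marker(ml: MLResult, convention: str = "midpoint") -> float:
    """NPM: timing of the 5-h nocturnal window (L5, or M5 for WT/sleep)."""
    return _marker(ml, 5, convention)


def day_phase_marker(ml: MLResult, convention: str = "midpoint") -> float:
    """DPM: timing of the 10-h diurnal window (M10, or L10 for WT/sleep)."""
    return _marker(ml, 10, convention)


def dm_npm(npm: float, center: float) -> float:
    """Difference from the darkness centre: circular distance (h) / 12, in [0, 1]."""
    return circ_dist(npm, center) / 12.0


def circadian_health_index(NRA: float, IS: float, DM_NPM: float) -> float:
    """CHI = (NRA + IS + (1 − DM-NPM)) / 3.

    1 for a healthy circadian system (high amplitude and stability, NPM on the
    darkness centre); 0 for an altered one (flat, unstable, 12 h out of phase).
    """
    for name, v in (("NRA", NRA), ("IS", IS), ("DM_NPM", DM_NPM)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    return (NRA + IS + (1.0 - DM_NPM)) / 3.0
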