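"""Synthetic 7-day multichannel recordings with controllable chronotype structure.

The generator emulates the phenomenology of a week of ambulatory circadian
monitoring in a young free-living cohort: a nightly sleep episode whose timing
carries the chronotype (phase offset), wrist temperature rising to a plateau
across sleep (peripheral vasodilation), activity and body position gated by
wakefulness, daytime lognormal light exposure (brighter days for earlier
chronotypes), a sinusoidal environmental temperature, a diary with reporting
noise, weekend sleep delay/extension, and sensor-off gaps.  Every stochastic
draw flows from one root seed through per-subject spawned generators, so
cohorts are reproducible bit-for-bit.

The shapes are phenomenological, not a thermoregulation model: they provide
ground truth (programmed phase, class labels, realized midsleep times) for
parameter-recovery testing of the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .circular import circ_mean, wrap_hours
from .diary import DiaryRecord
from .phase import SolarContext
from .timeseries import ChannelSeries, SubjectRecording, resample_to_grid

#: Recording start: a Monday at midnight in the late-autumn study window.
DEFAULT_START = datetime(2019, 11, 25, 0, 0)

_FREE_ONSET_WEEKDAYS = {4, 5}  # Friday, Saturday onsets are "free" nights

#: Default per-channel rhythm amplitudes (channel units).
DEFAULT_AMPLITUDE = {"WT": 2.5, "A": 70.0, "P": 42.0, "L": 2.0, "ET": 5.0}

#: Default per-channel noise scales.  WT/ET: additive SD in deg C; P: additive SD
#: in degrees; A: relative (gamma) dispersion; L: SD of log10 lux.
DEFAULT_NOISE = {"WT": 0.25, "A": 0.6, "P": 10.0, "L": 0.25, "ET": 0.3}


@dataclass
class SubjectParams:
    """Generator parameters for one synthetic subject.

    ``phase_offset`` shifts the whole behavioural cycle (the chronotype);
    ``day_jitter_sd`` jitters each night's onset (degrades IS);
    ``noise_sd`` scales within-day channel noise (raises IV);
    ``weekend_delay``/``weekend_extension`` shift and lengthen Friday- and
    Saturday-onset nights (create social jetlag and the MSFsc sleep-debt
    correction); ``sensor_off_rate`` injects diary-logged wrist-sensor gaps.
    """

    subject_id: str = "s000"
    phase_offset: float = 0.0           # hours
    amplitude: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDE))
    day_jitter_sd: float = 0.45         # hours
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    weekend_delay: float = 1.0          # hours
    weekend_extension: float = 1.0      # hours of extra weekend sleep
    sleep_duration: float = 7.5         # hours
    sleep_onset_base: float = 1.25      # clock hours (01:15)
    sensor_off_rate: float = 1.0        # events / week
    diary_noise_min: float = 5.0        # SD of diary-reported times, minutes
    nap_rate: float = 0.5               # naps / week
    light_gradient: float = 0.15        # log10 lux of extra daylight per hour earliness
    rest_activity_frac: float = 0.2     # nocturnal activity as fraction of waking rate
    rest_position_deg: float = 8.0      # mean body angle while asleep
    behavior_sd: float = 0.5            # log-scale SD of slow daytime behavioural drift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_jitter_sd < 0 or self.sensor_off_rate < 0:
            raise ValueError("rates and SDs must be non-negative")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")
        if not 4.0 < self.sleep_duration < 12.0:
            raise ValueError("sleep_duration must be in (4, 12) hours")


@dataclass
class SyntheticSubject:
    """A generated recording plus its ground truth."""

    params: SubjectParams
    recording: SubjectRecording
    raw: dict                      # variable -> raw pandas Series (logger rate)
    truth: dict                    # programmed phase, class, realized midsleeps


def _sleepiness(t_hours: np.ndarray, nights: list[tuple[float, float]],
                ramp: float) -> np.ndarray:
    """Smooth 0-1 sleep drive: 1 inside each night, raised-cosine edges.

    ``nights`` are (onset, offset) in hours since recording start; each
    transition is centred on the diary time with total width ``ramp``.
    """

    def smoothstep(u: np.ndarray) -> np.ndarray:
        u = np.clip(u, -0.5, 0.5)
        return 0.5 * (1.0 + np.sin(math.pi * u))

    sigma = np.zeros_like(t_hours)
    r = max(ramp, 1e-6)
    for onset, offset in nights:
        sigma += smoothstep((t_hours - onset) / r) - smoothstep((t_hours - offset) / r)
    return np.clip(sigma, 0.0, 1.0)


def _vasodilation_bump(t_hours: np.ndarray, nights: list[tuple[float, float]],
                       overhang: float = 1.2) -> np.ndarray:
    """Squared-cosine nocturnal bump peaking at each night's midsleep.

    Wrist temperature rises across sleep and peaks mid-sleep rather than
    sitting on a flat plateau; the bump spans the night plus ``overhang``
    hours on each side (vasodilation precedes sleep onset and outlasts wake).
    """
    bump = np.zeros_like(t_hours)
    for onset, offset in nights:
        mid = (onset + offset) / 2.0
        half = (offset - onset) / 2.0 + overhang
        u = (t_hours - mid) / half
        inside = np.abs(u) < 1.0
        bump[inside] = np.maximum(
            bump[inside], np.cos(0.5 * math.pi * u[inside]) ** 2
        )
    return bump


def _slow_noise(rng: np.random.Generator, n: int, sd: float,
                corr_epochs: int = 9) -> np.ndarray:
    """Zero-mean noise with ~1.5-h correlation on the 10-min grid."""
    if sd <= 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    k = np.exp(-0.5 * (np.arange(-3 * corr_epochs, 3 * corr_epochs + 1)
                       / corr_epochs) ** 2)
    k /= k.sum()
    smooth = np.convolve(white, k, mode="same")
    scale = smooth.std()
    return sd * smooth / scale if scale > 0 else np.zeros(n)


def generate_subject(
    params: SubjectParams,
    start: datetime = DEFAULT_START,
    site: SolarContext | None = None,
    n_days: int = 7,
) -> SyntheticSubject:
    """Generate one subject's 7-day multichannel recording, diary and truth.

    Wrist temperature, light and environmental temperature are produced at the
    native 10-min logger rate; activity and position at 30 s and resampled
    through the standard grid resampler (sum and mean respectively).
    """
    rng = np.random.default_rng(params.seed)
    site = site or SolarContext()

    # --- programmed nights -------------------------------------------------
    nights_h: list[tuple[float, float]] = []
    for d in range(n_days):
        date = start + timedelta(days=d)
        onset_clock = params.sleep_onset_base + params.phase_offset
        duration = params.sleep_duration
        if date.weekday() in _FREE_ONSET_WEEKDAYS:
            onset_clock += params.weekend_delay
            duration += params.weekend_extension
        onset_clock += rng.normal(0.0, params.day_jitter_sd) if params.day_jitter_sd else 0.0
        onset = d * 24.0 + onset_clock
        nights_h.append((onset, onset + duration))

    n10 = n_days * 144
    t10 = (np.arange(n10) + 0.5) / 6.0          # epoch centres, hours since start
    clock10 = (t10 + start.hour) % 24.0

    sigma = _sleepiness(t10, nights_h, ramp=0.5)
    bump = _vasodilation_bump(t10, nights_h)
    wake10 = 1.0 - sigma

    amp, noise = params.amplitude, params.noise_sd
    # slow behavioural drift shared by the willingness-dependent channels
    behav = _slow_noise(rng, n10, params.behavior_sd)

    # wrist temperature: squared-cosine nocturnal bump peaking at midsleep,
    # plus daytime vasodilation fluctuations tracking behaviour
    wt = 31.8 + amp["WT"] * bump + 0.8 * wake10 * behav
    if noise["WT"]:
        wt = wt + rng.normal(0.0, noise["WT"], n10)

    # environmental temperature: 24-h sinusoid peaking mid-afternoon, with
    # day-to-day weather offsets and room changes following behaviour
    day_offset = np.repeat(rng.normal(0.0, 1.5, n_days) if noise["ET"] else
                           np.zeros(n_days), 144)
    et = (19.0 + (amp["ET"] / 2.0) * np.cos(2.0 * math.pi * (clock10 - 15.0) / 24.0)
          + day_offset + 1.0 * behav)
    if noise["ET"]:
        et = et + rng.normal(0.0, noise["ET"], n10)

    # light: lognormal daylight while awake, dim indoor light after dark, and a
    # faint nocturnal residue while asleep (streetlight, devices)
    daylight = (clock10 >= site.sunrise) & (clock10 < site.sunset)
    day_level = 2.0 - params.light_gradient * params.phase_offset
    loglux = np.where(daylight, day_level, 1.3) + 0.8 * behav
    if noise["L"]:
        loglux = loglux + rng.normal(0.0, noise["L"], n10)
    dark_lux = np.power(10.0, -0.6 + (0.4 * rng.normal(0.0, 1.0, n10)
                                      if noise["L"] else 0.0))
    lux = wake10 * np.power(10.0, loglux) + sigma * dark_lux

    # activity & position at the 30-s logger rate
    n30 = n_days * 2880
    t30 = (np.arange(n30) + 0.5) / 120.0
    clock30 = (t30 + start.hour) % 24.0
    sigma30 = _sleepiness(t30, nights_h, ramp=0.5)
    wake30 = 1.0 - sigma30
    # ultradian modulation with exactly 7 cycles/day so noiseless days repeat
    ultra = 1.0 + 0.3 * np.sin(2.0 * math.pi * clock30 / (24.0 / 7.0))
    behav30 = np.repeat(behav, 20)
    gate = wake30 * np.exp(behav30) + params.rest_activity_frac * sigma30
    rate = (amp["A"] / 20.0) * gate * ultra  # per-30-s accumulation
    if noise["A"]:
        shape = 1.0 / noise["A"] ** 2
        rate = rate * rng.gamma(shape, 1.0 / shape, n30)
    activity = rate
    rest_angle = params.rest_position_deg
    pos = (wake30 * (rest_angle + amp["P"] + 12.0 * behav30)
           + (1.0 - wake30) * rest_angle)
    if noise["P"]:
        # posture blocks: sitting/standing changes on the ~10-min scale
        posture = np.repeat(rng.normal(0.0, 1.8 * noise["P"], n10), 20)
        pos = pos + wake30 * posture + rng.normal(0.0, noise["P"], n30)
    pos = np.clip(pos, 0.0, 90.0)

    # --- sensor-off gaps (wrist/arm sensors) -------------------------------
    sensor_off: list[tuple[datetime, datetime]] = []
    n_off = rng.poisson(params.sensor_off_rate) if params.sensor_off_rate else 0
    for _ in range(n_off):
        t0 = rng.uniform(0.0, n_days * 24.0 - 2.0)
        dur = rng.uniform(0.5, 1.5)
        a = (start + timedelta(hours=t0)).replace(microsecond=0)
        b = (start + timedelta(hours=t0 + dur)).replace(microsecond=0)
        sensor_off.append((a, b))
        g10 = (t10 >= t0) & (t10 < t0 + dur)
        # WT decays toward room temperature while off the wrist
        wt[g10] = 26.0 + (0.5 if noise["WT"] else 0.0) * rng.normal(0.0, 1.0, g10.sum())
        g30 = (t30 >= t0) & (t30 < t0 + dur)
        activity[g30] = 0.0
        pos[g30] = 0.0

    # --- diary -------------------------------------------------------------
    def report(hours: float) -> datetime:
        noise_h = (
            rng.normal(0.0, params.diary_noise_min / 60.0)
            if params.diary_noise_min
            else 0.0
        )
        ts = start + timedelta(hours=hours + noise_h)
        # diary granularity is one minute
        if ts.second >= 30:
            ts += timedelta(minutes=1)
        return ts.replace(second=0, microsecond=0)

    sleep_intervals = [(report(a), report(b)) for a, b in nights_h]
    naps: list[tuple[datetime, datetime]] = []
    n_naps = rng.poisson(params.nap_rate) if params.nap_rate else 0
    if n_naps:
        nap_days = rng.choice(n_days, size=min(n_naps, n_days), replace=False)
        for d in nap_days:
            nap_start = d * 24.0 + 14.5 + rng.normal(0.0, 0.7)
            nap_dur = rng.uniform(20.0, 60.0) / 60.0
            naps.append(
                (
                    (start + timedelta(hours=float(nap_start))).replace(microsecond=0),
                    (start + timedelta(hours=float(nap_start + nap_dur))).replace(
                        microsecond=0
                    ),
                )
            )
    merged_off: list[tuple[datetime, datetime]] = []
    for a, b in sorted(sensor_off):
        if merged_off and a <= merged_off[-1][1]:
            merged_off[-1] = (merged_off[-1][0], max(b, merged_off[-1][1]))
        else:
            merged_off.append((a, b))
    diary = DiaryRecord(
        subject_id=params.subject_id,
        sleep_intervals=sleep_intervals,
        nap_intervals=sorted(naps),
        sensor_off_intervals=merged_off,
    )

    # --- package as raw streams + resampled recording ----------------------
    grid10 = pd.date_range(start, periods=n10, freq="10min")
    grid30 = pd.date_range(start, periods=n30, freq="30s")
    raw = {
        "WT": pd.Series(wt, index=grid10),
        "L": pd.Series(lux, index=grid10),
        "ET": pd.Series(et, index=grid10),
        "A": pd.Series(activity, index=grid30),
        "P": pd.Series(pos, index=grid30),
    }
    channels = {
        "WT": ChannelSeries("WT", start, 10, wt, np.ones(n10, bool), "degC"),
        "L": ChannelSeries("L", start, 10, lux, np.ones(n10, bool), "lux"),
        "ET": ChannelSeries("ET", start, 10, et, np.ones(n10, bool), "degC"),
        "A": resample_to_grid(raw["A"], "A", method="sum", units="deg/min"),
        "P": resample_to_grid(raw["P"], "P", method="mean", units="deg"),
    }
    rec = SubjectRecording(
        subject_id=params.subject_id,
        channels=channels,
        diary=diary,
        site=site,
        weekday_of_start=start.weekday(),
    )

    midsleeps = [wrap_hours((a + b) / 2.0) for a, b in nights_h]
    truth = {
        "phase_offset": params.phase_offset,
        "midsleep_clock": midsleeps,
        "true_npm": circ_mean(midsleeps),
        "nights_hours": nights_h,
    }
    return SyntheticSubject(params=params, recording=rec, raw=raw, truth=truth)


#: Default class-conditional phase means (hours) for E / N / L subjects.
CLASS_PHASE_MEANS = {"E": -1.0, "N": 0.0, "L": 1.2}
CLASS_PHASE_SD = 0.3
CLASS_WEEKEND_DELAY = {"E": 0.5, "N": 1.0, "L": 1.5}


def _class_counts(n: int, mix: tuple[float, float, float]) -> dict[str, int]:
    raw = [n * m for m in mix]
    counts = [int(math.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(("E", "N", "L"), counts))


def generate_cohort(
    n: int = 50,
    class_mix: tuple[float, float, float] = (0.2, 0.6, 0.2),
    seed: int = 0,
    start: datetime = DEFAULT_START,
    site: SolarContext | None = None,
    **overrides,
) -> list[SyntheticSubject]:
    """Generate a cohort with E/N/L ground-truth labels in fixed proportions.

    Phase offsets are drawn per class around the class means; weekend delay is
    class-graded (later types delay more on free nights); per-subject
    day-jitter and noise scales vary mildly around their defaults.  Keyword
    overrides are applied to every subject's :class:`SubjectParams` after the
    per-class draws (e.g. ``day_jitter_sd=0`` for a noiseless cohort).
    """
    if n < 5:
        raise ValueError("cohort size must be at least 5")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    counts = _class_counts(n, class_mix)
    labels = [c for c in ("E", "N", "L") for _ in range(counts[c])]
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    subjects: list[SyntheticSubject] = []
    for i, (label, child) in enumerate(zip(labels, children)):
        crng = np.random.default_rng(child)
        phase = CLASS_PHASE_MEANS[label] + crng.normal(0.0, CLASS_PHASE_SD)
        jitter = max(float(crng.normal(0.45, 0.12)), 0.0)
        noise_scale = float(np.exp(crng.normal(0.0, 0.15)))
        noise = {k: v * noise_scale for k, v in DEFAULT_NOISE.items()}
        # between-subject physiology: rhythm amplitude and residual rest levels
        amplitude = {
            k: v * float(np.exp(crng.normal(0.0, 0.15)))
            for k, v in DEFAULT_AMPLITUDE.items()
        }
        rest_frac = float(np.clip(crng.normal(0.20, 0.07), 0.02, 0.5))
        rest_angle = float(np.clip(crng.normal(8.0, 3.0), 2.0, 20.0))
        params = SubjectParams(
            subject_id=f"s{i:03d}",
            phase_offset=float(phase),
            amplitude=amplitude,
            day_jitter_sd=jitter,
            noise_sd=noise,
            weekend_delay=CLASS_WEEKEND_DELAY[label],
            rest_activity_frac=rest_frac,
            rest_position_deg=rest_angle,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        if overrides:
            params = replace(params, **overrides)
        subj = generate_subject(params, start=start, site=site)
        subj.truth["class"] = label
        subjects.append(subj)
    return subjects
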