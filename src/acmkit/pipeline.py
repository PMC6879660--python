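"""End-to-end analysis: filter → waveforms → indexes → phase → classification.

``analyze_subject`` cleans every channel (diary sensor-off masking, then the
IQD rate-of-change filter), builds TAP and the binary sleep series, and
computes the per-variable waveform, IS, IV, M/L levels, RA and phase markers.
``analyze_cohort`` adds everything that is defined cohort-wide: NRA (the
5 %/95 % rescaling of RA), CFI, DM-NPM, CHI, the 20/60/20 chronotype
classification on the TAP night phase marker, the MSFsc-based classification,
and their agreement matrix.  Per-subject failures are quarantined and logged;
the run continues with the remaining subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chronotype as ct
from .circular import format_clock
from .diary import InsufficientDiaryError, binarize_sleep, msfsc
from .light_exposure import LightExposureTable, exposure_frame, time_in_bins
from .nonparametrics import (
    circadian_function_index,
    interdaily_stability,
    intradaily_variability,
    ml_levels,
    normalize_ra_cohort,
    relative_amplitude,
)
from .phase import (
    DEFAULT_SUNRISE,
    DEFAULT_SUNSET,
    SolarContext,
    circadian_health_index,
    day_phase_marker,
    dm_npm,
    night_phase_marker,
)
from .preprocess import MaskInterval, iqd_outlier_filter, log_transform_light, mask_intervals
from .tap import integrate_tap, normalize_channel, percentile_spec
from .timeseries import SubjectRecording, mean_waveform

ANALYSIS_VARIABLES = ("L", "ET", "WT", "A", "P", "TAP", "S")


@dataclass
class AnalysisConfig:
    """Run-wide settings; every run persists its resolved copy."""

    sunrise: str = DEFAULT_SUNRISE
    sunset: str = DEFAULT_SUNSET
    marker_convention: str = "midpoint"   # or "onset"
    iqd_mode: str = "values"              # or "diffs"
    toy_mode: bool = False
    norm_lower: float = 5.0               # TAP normalization percentiles
    norm_upper: float = 95.0
    tap_min_components: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_convention not in ("midpoint", "onset"):
            raise ValueError(f"bad marker_convention {self.marker_convention!r}")
        if self.iqd_mode not in ("values", "diffs"):
            raise ValueError(f"bad iqd_mode {self.iqd_mode!r}")
        if not 0 <= self.norm_lower < self.norm_upper <= 100:
            raise ValueError("normalization percentiles out of order")

    @property
    def site(self) -> SolarContext:
        return SolarContext.from_strings(sunrise=self.sunrise, sunset=self.sunset)


@dataclass
class SubjectResult:
    """Per-subject analysis output before cohort-wide normalization."""

    subject_id: str
    metrics: dict = field(default_factory=dict)      # variable -> dict
    waveforms: dict = field(default_factory=dict)    # variable -> DailyWaveform
    clean: dict = field(default_factory=dict)        # variable -> ChannelSeries
    light_table: LightExposureTable | None = None
    sleep_timing: object | None = None
    exclusions: list = field(default_factory=list)   # (variable, reason)


@dataclass
class CohortResult:
    """Cohort-level bundle: tidy summaries, assignments, agreement, logs."""

    subjects: list
    summaries: pd.DataFrame
    acm_classes: ct.Classification | None
    msf_classes: ct.Classification | None
    agreement: ct.AgreementMatrix | None
    sleep_timing: pd.DataFrame
    light: pd.DataFrame
    exclusions: dict


def analyze_subject(rec: SubjectRecording, config: AnalysisConfig | None = None) -> SubjectResult:
    """Clean one subject's channels and compute all per-subject quantities."""
    config = config or AnalysisConfig()
    res = SubjectResult(subject_id=rec.subject_id)
    toy = config.toy_mode

    masks = []
    if rec.diary is not None:
        masks = [
            MaskInterval(a, b, "sensor_off")
            for a, b in rec.diary.sensor_off_intervals
        ]

    clean: dict = {}
    for var in ("WT", "A", "P", "L", "ET"):
        ch = rec.channels.get(var)
        if ch is None:
            res.exclusions.append((var, "channel not recorded"))
            continue
        if not toy and not rec.analyzable(var):
            res.exclusions.append((var, f"recorded {ch.n_days:.2f} days (< 7)"))
            continue
        ch = mask_intervals(ch, masks)
        try:
            ch = iqd_outlier_filter(ch, mode=config.iqd_mode, toy_mode=toy)
        except ValueError as e:
            res.exclusions.append((var, f"filter failed: {e}"))
            continue
        clean[var] = ch

    raw_lux = clean.get("L")
    if raw_lux is not None:
        try:
            res.light_table = time_in_bins(raw_lux, subject_id=rec.subject_id)
        except ValueError as e:
            res.exclusions.append(("L", f"light binning failed: {e}"))
        clean["L"] = log_transform_light(raw_lux)

    if all(v in clean for v in ("WT", "A", "P")):
        try:
            norm = {
                v: normalize_channel(
                    clean[v],
                    percentile_spec(clean[v], config.norm_lower, config.norm_upper),
                )
                for v in ("WT", "A", "P")
            }
            clean["TAP"] = integrate_tap(
                norm["WT"], norm["A"], norm["P"],
                min_components=config.tap_min_components,
            )
        except ValueError as e:
            res.exclusions.append(("TAP", str(e)))
    else:
        res.exclusions.append(("TAP", "missing component channel"))

    if rec.diary is not None and clean:
        any_ch = next(iter(clean.values()))
        clean["S"] = binarize_sleep(
            rec.diary, any_ch.start, any_ch.n_epochs, any_ch.epoch_minutes
        )
        try:
            res.sleep_timing = msfsc(rec.diary)
        except InsufficientDiaryError as e:
            res.exclusions.append(("MSFsc", str(e)))

    res.clean = clean
    for var, ch in clean.items():
        try:
            wf = mean_waveform(ch, toy_mode=toy)
            ml = ml_levels(wf)
            metrics = {
                "IS": interdaily_stability(ch, toy_mode=toy),
                "IV": intradaily_variability(ch, toy_mode=toy),
                "M_level": ml.m_level,
                "L_level": ml.l_level,
                "M_hours": ml.m_hours,
                "L_hours": ml.l_hours,
                "RA": relative_amplitude(ml.m_level, ml.l_level),
                "NPM": night_phase_marker(ml, config.marker_convention),
                "DPM": day_phase_marker(ml, config.marker_convention),
            }
            res.metrics[var] = metrics
            res.waveforms[var] = wf
        except ValueError as e:
            res.exclusions.append((var, f"index computation failed: {e}"))
    return res


def analyze_cohort(
    recordings: list[SubjectRecording], config: AnalysisConfig | None = None
) -> CohortResult:
    """Run the full pipeline over a cohort and assemble the results bundle."""
    config = config or AnalysisConfig()
    subjects: list[SubjectResult] = []
    failed: dict[str, str] = {}
    for rec in recordings:
        try:
            subjects.append(analyze_subject(rec, config))
        except Exception as e:  # quarantine, keep going
            failed[rec.subject_id] = repr(e)
    if not subjects:
        raise RuntimeError(f"all {len(recordings)} subjects failed: {failed}")

    center = config.site.darkness_center
    rows = []
    for sub in subjects:
        for var, m in sub.metrics.items():
            rows.append({"subject_id": sub.subject_id, "variable": var, **m})
    tidy = pd.DataFrame(rows)

    # cohort-wide NRA per variable, then CFI / DM-NPM / CHI
    if not tidy.empty:
        tidy["NRA"] = np.nan
        for var, grp in tidy.groupby("variable"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small-cohort NRA warning
                try:
                    nra = normalize_ra_cohort(grp["RA"].to_numpy())
                except ValueError:
                    # no cohort spread in RA for this variable: rescaling is
                    # undefined, fall back to the clamped raw RA
                    warnings.warn(
                        f"{var}: degenerate cohort RA distribution; "
                        f"NRA falls back to clamped RA",
                        stacklevel=2,
                    )
                    nra = np.clip(grp["RA"].to_numpy(), 0.0, 1.0)
            tidy.loc[grp.index, "NRA"] = nra
        tidy["CFI"] = [
            circadian_function_index(r.IS, r.IV, r.NRA) for r in tidy.itertuples()
        ]
        tidy["DM_NPM"] = [dm_npm(v, center) for v in tidy["NPM"]]
        tidy["CHI"] = [
            circadian_health_index(r.NRA, r.IS, r.DM_NPM) for r in tidy.itertuples()
        ]
        tidy["NPM_clock"] = [format_clock(v) for v in tidy["NPM"]]
        tidy["DPM_clock"] = [format_clock(v) for v in tidy["DPM"]]

    acm_cls = msf_cls = agree = None
    tap_npms = {
        s.subject_id: s.metrics["TAP"]["NPM"] for s in subjects if "TAP" in s.metrics
    }
    if len(tap_npms) >= 5:
        acm_cls = ct.classify_by_npm(tap_npms)
    msf_vals = {
        s.subject_id: s.sleep_timing.msfsc
        for s in subjects
        if s.sleep_timing is not None
    }
    if len(msf_vals) >= 5:
        msf_cls = ct.classify_by_msfsc(msf_vals)
    if acm_cls is not None and msf_cls is not None:
        common = sorted(set(tap_npms) & set(msf_vals))
        if len(common) >= 5:
            a, m = acm_cls.as_dict(), msf_cls.as_dict()
            agree = ct.agreement(
                {s: a[s] for s in common}, {s: m[s] for s in common}
            )

    timing_rows = []
    for s in subjects:
        if s.sleep_timing is None:
            continue
        t = s.sleep_timing
        timing_rows.append(
            {
                "subject_id": s.subject_id,
                "onset_work": format_clock(t.onset_work),
                "offset_work": format_clock(t.offset_work),
                "onset_free": format_clock(t.onset_free),
                "offset_free": format_clock(t.offset_free),
                "SD_work_h": t.sd_work,
                "SD_free_h": t.sd_free,
                "MSW": format_clock(t.msw),
                "MSF": format_clock(t.msf),
                "MSFsc": format_clock(t.msfsc),
                "MSFsc_h": t.msfsc,
                "SJL_h": t.sjl,
            }
        )
    light = exposure_frame([s.light_table for s in subjects if s.light_table])

    exclusions = {
        "failed_subjects": failed,
        "per_subject": {
            s.subject_id: [list(e) for e in s.exclusions]
            for s in subjects
            if s.exclusions
        },
    }
    return CohortResult(
        subjects=subjects,
        summaries=tidy,
        acm_classes=acm_cls,
        msf_classes=msf_cls,
        agreement=agree,
        sleep_timing=pd.DataFrame(timing_rows),
        light=light,
        exclusions=exclusions,
    )


def write_results(result: CohortResult, outdir: str | Path,
                  config: AnalysisConfig | None = None) -> dict[str, Path]:
    """Write the bundle as CSV/JSON files; returns the paths written."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["results"] = outdir / "results.csv"
    result.summaries.to_csv(paths["results"], index=False)
    if result.acm_classes is not None:
        paths["assignments"] = outdir / "assignments.csv"
        df = result.acm_classes.to_frame().rename(columns={"label": "acm_class"})
        if result.msf_classes is not None:
            mdf = result.msf_classes.to_frame().rename(columns={"label": "msf_class"})
            df = df.merge(mdf[["subject_id", "msf_class"]], on="subject_id", how="left")
        df.to_csv(paths["assignments"], index=False)
    if result.agreement is not None:
        paths["agreement"] = outdir / "agreement.json"
        paths["agreement"].write_text(json.dumps(result.agreement.summary(), indent=2))
    paths["sleep_timing"] = outdir / "sleep_timing.csv"
    result.sleep_timing.to_csv(paths["sleep_timing"], index=False)
    paths["light"] = outdir / "light_exposure.csv"
    result.light.to_csv(paths["light"], index=False)
    paths["exclusions"] = outdir / "exclusions.json"
    paths["exclusions"].write_text(json.dumps(result.exclusions, indent=2))
    if config is not None:
        paths["config"] = outdir / "resolved_config.yaml"
        paths["config"].write_text(yaml.safe_dump(asdict(config)))
    return paths
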