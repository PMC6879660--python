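"""Logger-export CSV dialects, diary CSV, and the canonical long format.

Wearable loggers export timestamped CSVs in vendor dialects that differ in
column names, datetime format and decimal separator.  A :class:`LoggerDialect`
describes one export flavour; dialects can also be declared in a YAML config::

    dialects:
      wt:
        datetime_col: "Date/Time"
        value_col: "Value"
        datetime_format: "%d/%m/%y %H:%M:%S"
        decimal: ","
        skiprows: 1

The diary CSV is strict ISO-8601:
``subject_id,date,type,start,end`` with ``type`` in {sleep, nap, sensor_off}.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import pandas as pd
import yaml

from .diary import DiaryRecord
from .timeseries import ChannelSeries, SubjectRecording, resample_to_grid


@dataclass(frozen=True)
class LoggerDialect:
    """Column/format description of one logger CSV export flavour."""

    datetime_col: str
    value_col: str
    datetime_format: str = "%Y-%m-%d %H:%M:%S"
    decimal: str = "."
    skiprows: int = 0


#: Built-in dialects: a thermochron-style export (European decimal comma,
#: two-digit year) and a pendant-logger-style export.
DIALECTS = {
    "ibutton": LoggerDialect(
        datetime_col="Date/Time",
        value_col="Value",
        datetime_format="%d/%m/%y %H:%M:%S",
        decimal=",",
        skiprows=0,
    ),
    "hobo": LoggerDialect(
        datetime_col="Date Time",
        value_col="Value",
        datetime_format="%m/%d/%y %I:%M:%S %p",
        decimal=".",
        skiprows=0,
    ),
    "plain": LoggerDialect(datetime_col="timestamp", value_col="value"),
}


def read_logger_csv(path: str | Path, dialect: LoggerDialect | str) -> pd.Series:
    """Read one logger CSV into a timestamp-indexed value Series."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    df = pd.read_csv(path, skiprows=dialect.skiprows, decimal=dialect.decimal)
    if dialect.datetime_col not in df.columns or dialect.value_col not in df.columns:
        raise ValueError(
            f"{path}: expected columns {dialect.datetime_col!r}, "
            f"{dialect.value_col!r}; found {list(df.columns)}"
        )
    ts = pd.to_datetime(df[dialect.datetime_col], format=dialect.datetime_format)
    return pd.Series(df[dialect.value_col].to_numpy(dtype=float), index=ts)


def write_logger_csv(
    series: pd.Series, path: str | Path, dialect: LoggerDialect | str
) -> None:
    """Write a timestamp-indexed Series in the given logger dialect."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    ts = [t.strftime(dialect.datetime_format) for t in series.index]
    vals = [f"{v:.4f}" for v in series.to_numpy(dtype=float)]
    if dialect.decimal != ".":
        vals = [v.replace(".", dialect.decimal) for v in vals]
    df = pd.DataFrame({dialect.datetime_col: ts, dialect.value_col: vals})
    df.to_csv(path, index=False)


def load_dialects(config_path: str | Path) -> dict[str, LoggerDialect]:
    """Read a ``dialects:`` mapping from a YAML config file."""
    cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    out = dict(DIALECTS)
    for name, spec in (cfg.get("dialects") or {}).items():
        out[name] = LoggerDialect(**spec)
    return out


# ---------------------------------------------------------------------------
# diary CSV

DIARY_COLUMNS = ["subject_id", "date", "type", "start", "end"]
_ISO = "%Y-%m-%dT%H:%M:%S"


def write_diary_csv(diary: DiaryRecord, path: str | Path) -> None:
    rows = []
    for kind, intervals in (
        ("sleep", diary.sleep_intervals),
        ("nap", diary.nap_intervals),
        ("sensor_off", diary.sensor_off_intervals),
    ):
        for a, b in intervals:
            rows.append(
                {
                    "subject_id": diary.subject_id,
                    "date": a.date().isoformat(),
                    "type": kind,
                    "start": a.strftime(_ISO),
                    "end": b.strftime(_ISO),
                }
            )
    pd.DataFrame(rows, columns=DIARY_COLUMNS).to_csv(path, index=False)


def read_diary_csv(path: str | Path) -> DiaryRecord:
    df = pd.read_csv(path)
    missing = set(DIARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: diary CSV missing columns {sorted(missing)}")
    buckets: dict[str, list] = {"sleep": [], "nap": [], "sensor_off": []}
    sid = None
    for row in df.itertuples():
        if row.type not in buckets:
            raise ValueError(f"{path}: unknown diary entry type {row.type!r}")
        a = datetime.strptime(row.start, _ISO)
        b = datetime.strptime(row.end, _ISO)
        buckets[row.type].append((a, b))
        sid = row.subject_id
    return DiaryRecord(
        subject_id=str(sid),
        sleep_intervals=buckets["sleep"],
        nap_intervals=buckets["nap"],
        sensor_off_intervals=buckets["sensor_off"],
    )


# ---------------------------------------------------------------------------
# per-subject directories: the layout `acm simulate` writes and `acm run` reads

_CHANNEL_FILES = {
    "WT": ("wt.csv", "ibutton", "mean", "degC"),
    "A": ("activity.csv", "hobo", "sum", "deg/min"),
    "P": ("position.csv", "hobo", "mean", "deg"),
    "L": ("light.csv", "hobo", "mean", "lux"),
    "ET": ("envtemp.csv", "hobo", "mean", "degC"),
}


def write_subject_dir(
    subject_dir: str | Path, raw: dict[str, pd.Series], diary: DiaryRecord
) -> None:
    """Write one subject's raw logger CSVs plus diary into a directory."""
    d = Path(subject_dir)
    d.mkdir(parents=True, exist_ok=True)
    for var, series in raw.items():
        fname, dialect, _, _ = _CHANNEL_FILES[var]
        write_logger_csv(series, d / fname, dialect)
    write_diary_csv(diary, d / "diary.csv")


def read_subject_dir(subject_dir: str | Path) -> SubjectRecording:
    """Read a subject directory back into a resampled :class:`SubjectRecording`."""
    d = Path(subject_dir)
    channels: dict[str, ChannelSeries] = {}
    for var, (fname, dialect, method, units) in _CHANNEL_FILES.items():
        f = d / fname
        if not f.exists():
            continue
        raw = read_logger_csv(f, dialect)
        channels[var] = resample_to_grid(raw, var, method=method, units=units)
    diary = None
    if (d / "diary.csv").exists():
        diary = read_diary_csv(d / "diary.csv")
    start_wd = 0
    if channels:
        start_wd = next(iter(channels.values())).start.weekday()
    return SubjectRecording(
        subject_id=d.name, channels=channels, diary=diary, weekday_of_start=start_wd
    )


# ---------------------------------------------------------------------------
# canonical long format

def write_long_csv(recordings: list[SubjectRecording], path: str | Path) -> None:
    """Canonical long CSV: subject_id, variable, epoch_start, value, valid."""
    frames = []
    for rec in recordings:
        for var, ch in rec.channels.items():
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "variable": var,
                        "epoch_start": ch.epoch_starts().strftime(_ISO),
                        "value": ch.values,
                        "valid": ch.valid.astype(int),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
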