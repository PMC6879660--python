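"""Figures: group mean waveforms with SEM bands and double-plotted actograms.

Actograms follow chronobiology convention: one row per day, 48 h wide (each
day re-plots the following day), with epochs beyond the variable-appropriate
tercile threshold marked.  Rest is marked by the *first* tercile (lowest third)
for day-peaking variables and by the *third* tercile (highest third) for wrist
temperature and sleep, whose values are high at night.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .timeseries import ChannelSeries, DailyWaveform, NOCTURNAL_ACROPHASE  # noqa: E402

GROUP_COLORS = {"E": "#e6b422", "N": "#222222", "L": "#1f5fbf"}


def tercile_threshold(series: ChannelSeries) -> tuple[float, str]:
    """(threshold, side): side 'above' marks values >= the 67th percentile
    (WT, S), 'below' marks values <= the 33rd percentile (everything else)."""
    vals = series.valid_values()
    if vals.size == 0:
        raise ValueError("no valid epochs for tercile threshold")
    if series.variable in NOCTURNAL_ACROPHASE:
        return float(np.percentile(vals, 100 * 2 / 3)), "above"
    return float(np.percentile(vals, 100 / 3)), "below"


def plot_actogram(series: ChannelSeries, ax=None, title: str | None = None):
    """Double-plotted raster of one subject-week; marked epochs are 'rest'."""
    thr, side = tercile_threshold(series)
    p = series.slots_per_day
    n_days = int(np.ceil(series.n_days))
    padded = np.full(n_days * p, np.nan)
    padded[: series.n_epochs] = np.where(series.valid, series.values, np.nan)
    days = padded.reshape(n_days, p)

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 * n_days + 1.2))
    for d in range(n_days):
        row = np.concatenate(
            [days[d], days[d + 1] if d + 1 < n_days else np.full(p, np.nan)]
        )
        marked = (row >= thr) if side == "above" else (row <= thr)
        xs = np.arange(2 * p) / p * 24.0
        y0 = n_days - d
        ax.fill_between(
            xs, y0 - 0.9, y0, where=marked & np.isfinite(row),
            step="post", color="black", linewidth=0,
        )
        gap = ~np.isfinite(row)
        if gap.any():
            ax.fill_between(
                xs, y0 - 0.9, y0, where=gap, step="post",
                color="0.85", linewidth=0,
            )
    ax.set_xlim(0, 48)
    ax.set_xticks(range(0, 49, 6))
    ax.set_xlabel("time of day (h, double-plotted)")
    ax.set_ylim(0.0, n_days + 0.2)
    ax.set_yticks([n_days - d - 0.5 + 0.05 for d in range(n_days)])
    ax.set_yticklabels([f"day {d + 1}" for d in range(n_days)])
    ax.set_title(title or f"{series.variable} actogram (tercile-marked rest)")
    return ax


def plot_group_waveforms(
    group_waveforms: dict[str, DailyWaveform], variable: str, ax=None
):
    """Overlay per-group mean waveforms with SEM bands (groups keyed E/N/L)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    for label, wf in group_waveforms.items():
        hours = wf.slot_clock_hours()
        color = GROUP_COLORS.get(label)
        ax.plot(hours, wf.values, label=f"{label}-type", color=color, lw=1.4)
        if wf.sem is not None:
            lo, hi = wf.values - wf.sem, wf.values + wf.sem
            ax.fill_between(hours, lo, hi, alpha=0.25, color=color, linewidth=0)
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 4))
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel(variable)
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(f"{variable}: group mean waveform ± SEM")
    return ax


def save_figure(ax, path) -> None:
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
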