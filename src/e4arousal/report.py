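"""Dashboard-style per-day reports and cohort collection summaries.

The day dashboard stacks five panels on one local-time axis — movement (g),
skin temperature (°C), SCL (µS) with observation marks, HR (bpm) and HRV
RMSSD (ms) — with off-wrist spans shaded, a 5-minute moving-average overlay
and a day-median reference line per panel.  Rendering is deterministic given
the inputs.
"""

from __future__ import annotations

import base64
from datetime import datetime
from pathlib import Path
from zoneinfo import ZoneInfo

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.dates as mdates
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .e4io import E4Session
from .features import rmssd
from .frames import ProcessedDay
from .quality import OFF_WRIST

__all__ = [
    "render_day",
    "hr_distribution_report",
    "collection_summary",
    "five_number_summary",
]

EVENT_COLORS = {"green": "#2ca02c", "orange": "#ff7f0e", "red": "#d62728"}
SETTING_TARGETS_H = {"clinic": 60.0, "daycare": 35.0}


def _hrv_series(day: ProcessedDay, hop_s: float = 60.0, window_s: float = 300.0, min_beats: int = 10):
    start, end = day.recording_window()
    t = np.arange(start, end - window_s + 1e-9, hop_s)
    vals = np.array([rmssd(day.session.ibi, s, s + window_s, min_beats) for s in t])
    return t + window_s / 2, vals


def _overlay(values: np.ndarray, rate: float, window_s: float = 300.0) -> np.ndarray:
    w = max(int(round(window_s * rate)), 1)
    v = pd.Series(values)
    return v.rolling(w, center=True, min_periods=max(w // 4, 1)).mean().to_numpy()


def render_day(
    day: ProcessedDay,
    events=(),
    out_png: str | Path | None = None,
    out_html: str | Path | None = None,
):
    """Five stacked dashboard panels for one participant-day.

    Event marks (colored by traffic-light code) appear on the SCL panel;
    off-wrist spans are shaded on every panel.  An empty day produces empty
    axes, not an exception.  Returns the matplotlib Figure.
    """
    tz = ZoneInfo(day.session.timezone)

    def as_dates(ts: np.ndarray):
        return [datetime.fromtimestamp(t, tz) for t in np.asarray(ts)]

    panels: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    panels.append(("movement", "g", day.movement.times(), day.movement.values))
    temp = day.session["TEMP"]
    panels.append(("skin temperature", "°C", temp.times(), temp.values))
    panels.append(("SCL", "µS", day.scl.times(), day.scl.values))
    panels.append(("HR", "bpm", day.hr.times(), day.hr.values))
    hrv_t, hrv_v = _hrv_series(day) if len(day.session.ibi) else (np.empty(0), np.empty(0))
    panels.append(("HRV (RMSSD)", "ms", hrv_t, hrv_v))

    fig, axes = plt.subplots(5, 1, figsize=(12, 10), sharex=True)
    off_spans = day.mask.spans(OFF_WRIST)
    for ax, (title, unit, t, v) in zip(axes, panels):
        if len(t):
            ax.plot(as_dates(t), v, lw=0.6, color="#1f77b4")
            finite = v[np.isfinite(v)]
            if len(finite):
                ax.axhline(np.median(finite), color="gray", lw=0.7, ls=":", label="day median")
            if title in ("movement", "SCL", "HR") and len(v) > 10:
                rate = len(t) / max(t[-1] - t[0], 1.0)
                ax.plot(as_dates(t), _overlay(v, rate), lw=1.2, color="#17becf")
        for s, e in off_spans:
            ax.axvspan(
                datetime.fromtimestamp(s, tz), datetime.fromtimestamp(e, tz),
                color="0.85", zorder=0,
            )
        ax.set_ylabel(f"{title}\n({unit})", fontsize=8)
    for e in events:
        axes[2].axvline(
            datetime.fromtimestamp(e.timestamp, tz),
            color=EVENT_COLORS.get(e.color, "k"), lw=1.0, alpha=0.8,
        )
    axes[-1].xaxis.set_major_formatter(mdates.DateFormatter("%H:%M", tz=tz))
    axes[-1].set_xlabel(f"local time ({day.session.timezone})")
    fig.suptitle(
        f"{day.participant_id} — day {day.day_index} ({day.session.setting})", fontsize=10
    )
    fig.tight_layout()

    if out_png is not None:
        fig.savefig(out_png, dpi=110)
    if out_html is not None:
        _write_html(fig, day, events, Path(out_html))
    return fig


def _write_html(fig, day: ProcessedDay, events, path: Path) -> None:
    import io as _io

    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110)
    img = base64.b64encode(buf.getvalue()).decode()
    tz = ZoneInfo(day.session.timezone)
    rows = "".join(
        f"<tr><td>{datetime.fromtimestamp(e.timestamp, tz):%H:%M}</td>"
        f"<td>{e.color}</td><td>{e.description}</td><td>{e.observer}</td></tr>"
        for e in sorted(events, key=lambda e: e.timestamp)
    )
    path.write_text(
        "<html><body>"
        f"<h2>{day.participant_id} day {day.day_index}</h2>"
        f'<img src="data:image/png;base64,{img}"/>'
        "<h3>Observations</h3>"
        f"<table border=1><tr><th>time</th><th>code</th><th>description</th><th>observer</th></tr>{rows}</table>"
        "</body></html>"
    )


def five_number_summary(values: np.ndarray) -> dict[str, float]:
    """min, Q1, median, Q3, max with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return {k: float("nan") for k in ("min", "q1", "median", "q3", "max")}
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def hr_distribution_report(days: list[ProcessedDay], age: int) -> pd.DataFrame:
    """Per-day boxplot five-number summaries of valid (invalidated) HR.

    Flags a day when its interquartile range leaves the pediatric norm band
    for the age (80–120 bpm under 12 y, 60–100 bpm from 12 y) — quartiles
    rather than extremes, so isolated noise samples do not flag a day but a
    sustained artifact (e.g. off-wrist HR left uninvalidated) does.
    """
    from .synth import hr_norm_band

    lo, hi = hr_norm_band(age)
    rows = []
    for day in sorted(days, key=lambda d: d.day_index):
        s = five_number_summary(day.hr.values)
        s["day_index"] = day.day_index
        s["participant_id"] = day.participant_id
        s["outside_norm_range"] = bool(
            np.isfinite(s["q1"]) and (s["q1"] < lo or s["q3"] > hi)
        )
        rows.append(s)
    return pd.DataFrame(rows)


def collection_summary(sessions: list[E4Session], targets: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-setting mean recorded hours per child and percent of the target.

    Targets default to the study aims: 60 h per child at the clinic, 35 h at
    the daycare unit.  Percent-of-target is scale-invariant.
    """
    targets = targets or SETTING_TARGETS_H
    per_child: dict[str, dict] = {}
    for s in sessions:
        rec = per_child.setdefault(s.participant_id, {"setting": s.setting, "hours": 0.0})
        rec["hours"] += s["EDA"].duration / 3600.0
    df = pd.DataFrame.from_dict(per_child, orient="index")
    rows = []
    for setting, grp in df.groupby("setting"):
        mean_h = float(grp["hours"].mean())
        target = targets.get(setting, float("nan"))
        rows.append(
            {
                "setting": setting,
                "n_children": len(grp),
                "mean_hours": mean_h,
                "target_hours": target,
                "pct_of_target": round(100.0 * mean_h / target, 1),
            }
        )
    return pd.DataFrame(rows)
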