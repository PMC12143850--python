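"""Incident-aligned 5-minute frames with within-person matched references.

The inference-preparation procedure:

1.  Every red (physical aggression) observation anchors a 5-minute frame
    starting at the recorded incident time.  Red events closer together than
    one frame are merged into one frame anchored at the earliest, so a single
    escalation is not double-counted.
2.  For each incident, candidate *reference* frames are taken from the same
    participant at the same local clock time on every other wearing day with
    recording.
3.  A candidate reference is excluded when aggressive behavior was also
    observed during its window (aggression overlap, judged with the events'
    timestamp uncertainty), and any frame — incident or reference — with more
    than 75% EDA artifacts is excluded as unreliable.
4.  Each retained frame is summarized (mean movement, HR, SCL over valid
    samples; PPM), and incidents are paired with the mean of their retained
    references, one row per incident per measure.

Exclusion accounting conserves counts: every candidate is retained or
excluded with exactly one reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .e4io import E4Session, SignalChannel
from .features import DerivedSeries, ScrPeak, peaks_per_minute
from .observations import ObservationEvent, ObservationLog
from .quality import OFF_WRIST, QualityMask, VALID

__all__ = [
    "MEASURES",
    "FrameConfig",
    "ProcessedDay",
    "AnalysisFrame",
    "PairedFrameSet",
    "extract_incident_frames",
    "build_reference_frames",
    "filter_artifact_frames",
    "summarize_frame",
    "assemble_pairs",
    "frame_ledger",
    "exclusion_summary",
]

#: the four measures entering inference
MEASURES = ("movement_g", "hr_bpm", "scl_uS", "ppm")

FRAME_S = 300.0

REASON_AGGRESSION = "aggression_overlap"
REASON_ARTIFACT = "artifact_gt_75"
REASON_MISSING = "missing_data"


@dataclass
class FrameConfig:
    frame_s: float = FRAME_S
    merge_window_s: float = 300.0
    artifact_threshold: float = 0.75  # strictly-greater-than excludes
    min_coverage: float = 0.8  # frames with less of the window recorded are dropped
    aggression_colors: tuple[str, ...] = ("red", "orange")
    #: how long an observed aggression episode is taken to last for the
    #: reference-overlap test; the log records onsets only, and an episode is
    #: treated as occupying one frame length just as incidents are
    event_duration_s: float = 300.0
    ppm_denominator: str = "valid"  # "valid" | "wall"


@dataclass
class ProcessedDay:
    """One participant-day after quality masking and feature derivation."""

    session: E4Session
    mask: QualityMask  # EDA mask including off-wrist labeling
    hr: SignalChannel  # off-wrist-invalidated
    movement: DerivedSeries
    scl: DerivedSeries
    peaks: list[ScrPeak]

    @property
    def participant_id(self) -> str:
        return self.session.participant_id

    @property
    def day_index(self) -> int:
        return self.session.day_index

    def recording_window(self) -> tuple[float, float]:
        eda = self.session["EDA"]
        return eda.start_time, eda.end_time


@dataclass
class AnalysisFrame:
    """A 5-minute incident or reference window with per-measure summaries."""

    participant_id: str
    kind: str  # "incident" | "reference"
    start: float  # UTC seconds; window is [start, start + FRAME_S)
    day_index: int
    anchor_event: ObservationEvent | None = None
    artifact_fraction: float = float("nan")
    coverage: float = 0.0
    summaries: dict[str, float] = field(default_factory=dict)
    exclusion_reason: str | None = None

    @property
    def end(self) -> float:
        return self.start + FRAME_S

    @property
    def usable(self) -> bool:
        return self.exclusion_reason is None


@dataclass
class PairedFrameSet:
    """One incident with its retained and excluded reference frames."""

    incident: AnalysisFrame
    references: list[AnalysisFrame] = field(default_factory=list)
    excluded_references: list[AnalysisFrame] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return self.incident.usable and len(self.references) > 0

    def reference_mean(self) -> dict[str, float]:
        """Per-measure mean over retained references (NaN-aware)."""
        out = {}
        for m in MEASURES:
            vals = [
                r.summaries.get(m, float("nan"))
                for r in self.references
                if np.isfinite(r.summaries.get(m, float("nan")))
            ]
            out[m] = float(np.mean(vals)) if vals else float("nan")
        return out

    def candidate_count(self) -> int:
        return len(self.references) + len(self.excluded_references)


# ---------------------------------------------------------------------------


def _window_stats(day: ProcessedDay, start: float, end: float) -> tuple[float, float]:
    """(artifact_fraction, coverage) of the EDA signal over [start, end)."""
    eda = day.session["EDA"]
    t = eda.times()
    inside = (t >= start) & (t < end)
    n_inside = int(inside.sum())
    n_expected = int(round((end - start) * eda.rate))
    coverage = n_inside / n_expected if n_expected else 0.0
    if n_inside == 0:
        return float("nan"), 0.0
    labels = day.mask.labels_at(t[inside])
    frac = float(np.mean(labels != VALID))
    return frac, coverage


def summarize_frame(
    day: ProcessedDay, start: float, end: float, config: FrameConfig | None = None
) -> dict[str, float]:
    """Per-measure summaries over valid samples in [start, end).

    Each measure goes missing independently when its own source carries no
    valid sample in the window; PPM divides the peak count by valid (default)
    or wall minutes.  A window that is entirely off-wrist has no wearer, so
    every summary (including movement) is missing.
    """
    cfg = config or FrameConfig()
    eda = day.session["EDA"]
    t = eda.times()
    inside = (t >= start) & (t < end)
    if not inside.any() or np.all(day.mask.labels_at(t[inside]) == OFF_WRIST):
        return {m: float("nan") for m in MEASURES}
    out = {
        "movement_g": day.movement.window_mean(start, end),
        "hr_bpm": _masked_channel_mean(day.hr, start, end),
        "scl_uS": day.scl.window_mean(start, end),
    }
    artifact_fraction, coverage = _window_stats(day, start, end)
    if cfg.ppm_denominator == "valid":
        valid_fraction = (1.0 - artifact_fraction) * coverage
    else:
        valid_fraction = 1.0
    out["ppm"] = peaks_per_minute(day.peaks, start, end, valid_fraction)
    return out


def _masked_channel_mean(ch: SignalChannel, start: float, end: float) -> float:
    seg = ch.slice_window(start, end)
    if len(seg) == 0 or not np.isfinite(seg).any():
        return float("nan")
    return float(np.nanmean(seg))


def _make_frame(
    day: ProcessedDay,
    kind: str,
    start: float,
    cfg: FrameConfig,
    anchor: ObservationEvent | None = None,
) -> AnalysisFrame:
    end = start + cfg.frame_s
    artifact_fraction, coverage = _window_stats(day, start, end)
    frame = AnalysisFrame(
        participant_id=day.participant_id,
        kind=kind,
        start=start,
        day_index=day.day_index,
        anchor_event=anchor,
        artifact_fraction=artifact_fraction,
        coverage=coverage,
    )
    if coverage < cfg.min_coverage:
        frame.exclusion_reason = REASON_MISSING
        return frame
    frame.summaries = summarize_frame(day, start, end, cfg)
    return frame


def _merge_red_anchors(events: Sequence[ObservationEvent], merge_window_s: float):
    """Earliest-anchored merge of red events within one frame length."""
    anchors: list[ObservationEvent] = []
    last: dict[str, float] = {}
    for e in sorted(events, key=lambda e: (e.participant_id, e.timestamp)):
        prev = last.get(e.participant_id)
        if prev is not None and e.timestamp - prev < merge_window_s:
            continue
        anchors.append(e)
        last[e.participant_id] = e.timestamp
    return anchors


def extract_incident_frames(
    log: ObservationLog,
    days: dict[tuple[str, int], ProcessedDay],
    config: FrameConfig | None = None,
) -> list[AnalysisFrame]:
    """One incident frame per (merged) red event with wearable coverage.

    The recorded incident time is the start of the 5-minute frame.  Events
    without overlapping recording — or with less than the configured share of
    the window recorded — yield a frame excluded as ``missing_data``.
    """
    cfg = config or FrameConfig()
    reds = [e for e in log.events if e.color == "red"]
    frames: list[AnalysisFrame] = []
    for event in _merge_red_anchors(reds, cfg.merge_window_s):
        day = _find_day(days, event.participant_id, event.timestamp, cfg.frame_s)
        if day is None:
            frames.append(
                AnalysisFrame(
                    participant_id=event.participant_id,
                    kind="incident",
                    start=event.timestamp,
                    day_index=-1,
                    anchor_event=event,
                    exclusion_reason=REASON_MISSING,
                )
            )
            continue
        frames.append(_make_frame(day, "incident", event.timestamp, cfg, anchor=event))
    return frames


def _find_day(days, pid: str, t: float, frame_s: float) -> ProcessedDay | None:
    best, best_overlap = None, 0.0
    for (p, _d), day in days.items():
        if p != pid:
            continue
        s, e = day.recording_window()
        overlap = min(e, t + frame_s) - max(s, t)
        if overlap > best_overlap:
            best, best_overlap = day, overlap
    return best


def _same_clock_start(incident_start: float, from_day: ProcessedDay, to_day: ProcessedDay) -> float:
    """UTC start on ``to_day`` matching the incident's local wall-clock time."""
    tz = ZoneInfo(from_day.session.timezone)
    local = datetime.fromtimestamp(incident_start, tz)
    target = datetime.combine(to_day.session.local_date(), local.timetz())
    return target.timestamp()


def build_reference_frames(
    incident: AnalysisFrame,
    days: dict[tuple[str, int], ProcessedDay],
    log: ObservationLog,
    config: FrameConfig | None = None,
) -> PairedFrameSet:
    """Same-participant, same-clock-time reference frames from other days.

    Candidates come from every other wearing day with recording.  Exclusion
    reasons, applied in order: ``missing_data`` (insufficient recording of the
    window), ``aggression_overlap`` (an aggression episode — onset to onset
    plus the configured episode duration, widened by the timestamp
    uncertainty — overlaps the window), ``artifact_gt_75``.
    """
    cfg = config or FrameConfig()
    pset = PairedFrameSet(incident=incident)
    pid = incident.participant_id
    incident_day = days.get((pid, incident.day_index))
    if incident_day is None:
        return pset
    agg_events = log.for_participant(pid, colors=cfg.aggression_colors)
    for (p, d), day in sorted(days.items()):
        if p != pid or d == incident.day_index:
            continue
        start = _same_clock_start(incident.start, incident_day, day)
        frame = _make_frame(day, "reference", start, cfg)
        if frame.exclusion_reason is None:
            if any(
                e.timestamp + cfg.event_duration_s + e.uncertainty_s > start
                and e.timestamp - e.uncertainty_s < start + cfg.frame_s
                for e in agg_events
            ):
                frame.exclusion_reason = REASON_AGGRESSION
                frame.summaries = {}
        if frame.exclusion_reason is None and frame.artifact_fraction > cfg.artifact_threshold:
            frame.exclusion_reason = REASON_ARTIFACT
            frame.summaries = {}
        (pset.references if frame.usable else pset.excluded_references).append(frame)
    return pset


def filter_artifact_frames(
    frames: Sequence[AnalysisFrame], threshold: float = 0.75
) -> tuple[list[AnalysisFrame], list[AnalysisFrame]]:
    """Partition frames by the EDA artifact filter.

    A frame is excluded when *more than* ``threshold`` of its EDA epochs are
    artifact/off-wrist — the inequality is strict, so a frame at exactly the
    threshold is retained.  Applies to incident and reference frames alike.
    """
    retained, excluded = [], []
    for f in frames:
        if np.isfinite(f.artifact_fraction) and f.artifact_fraction > threshold:
            f.exclusion_reason = REASON_ARTIFACT
            excluded.append(f)
        else:
            retained.append(f)
    return retained, excluded


def assemble_pairs(paired_sets: Sequence[PairedFrameSet]) -> dict[str, pd.DataFrame]:
    """Per-measure paired table: one row per usable incident.

    A row requires a usable incident, at least one retained reference, and
    non-missing values on both sides *for that measure* — a measure missing on
    one side drops the row for that measure only.
    """
    tables: dict[str, list[dict]] = {m: [] for m in MEASURES}
    for ps in paired_sets:
        if not ps.usable:
            continue
        ref_mean = ps.reference_mean()
        for m in MEASURES:
            inc = ps.incident.summaries.get(m, float("nan"))
            ref = ref_mean[m]
            if np.isfinite(inc) and np.isfinite(ref):
                tables[m].append(
                    {
                        "participant_id": ps.incident.participant_id,
                        "anchor_utc": ps.incident.start,
                        "incident": inc,
                        "reference": ref,
                        "n_references": len(ps.references),
                    }
                )
    return {m: pd.DataFrame(rows) for m, rows in tables.items()}


def frame_ledger(paired_sets: Sequence[PairedFrameSet]) -> pd.DataFrame:
    """One row per frame (incidents and references) with full bookkeeping."""
    rows = []
    for ps in paired_sets:
        for f in [ps.incident] + ps.references + ps.excluded_references:
            row = {
                "participant_id": f.participant_id,
                "kind": f.kind,
                "day_index": f.day_index,
                "window_start_utc": f.start,
                "window_end_utc": f.end,
                "artifact_fraction": f.artifact_fraction,
                "coverage": f.coverage,
                "exclusion_reason": f.exclusion_reason or "",
            }
            for m in MEASURES:
                row[m] = f.summaries.get(m, float("nan"))
            rows.append(row)
    return pd.DataFrame(rows)


def _pct(n: int, d: int) -> float:
    return round(100.0 * n / d, 1) if d else float("nan")


def exclusion_summary(paired_sets: Sequence[PairedFrameSet]) -> dict:
    """Exclusion accounting across all frames.

    Reports candidate reference counts with the share excluded for aggression
    overlap, and total frame counts with the share excluded by the artifact
    filter; percentages to one decimal.  Counts conserve: every candidate is
    retained or excluded with exactly one reason.
    """
    ref_candidates = sum(ps.candidate_count() for ps in paired_sets)
    ref_aggression = sum(
        sum(1 for f in ps.excluded_references if f.exclusion_reason == REASON_AGGRESSION)
        for ps in paired_sets
    )
    all_frames = [ps.incident for ps in paired_sets] + [
        f for ps in paired_sets for f in ps.references + ps.excluded_references
    ]
    n_frames = len(all_frames)
    n_artifact = sum(1 for f in all_frames if f.exclusion_reason == REASON_ARTIFACT)
    n_missing = sum(1 for f in all_frames if f.exclusion_reason == REASON_MISSING)
    n_retained = sum(1 for f in all_frames if f.usable)
    assert n_retained + n_artifact + n_missing + ref_aggression + sum(
        1 for ps in paired_sets if ps.incident.exclusion_reason == REASON_AGGRESSION
    ) == n_frames, "exclusion accounting must conserve frame counts"
    return {
        "reference_candidates": ref_candidates,
        "reference_excluded_aggression": ref_aggression,
        "reference_excluded_aggression_pct": _pct(ref_aggression, ref_candidates),
        "frames_total": n_frames,
        "frames_excluded_artifact": n_artifact,
        "frames_excluded_artifact_pct": _pct(n_artifact, n_frames),
        "frames_excluded_missing": n_missing,
        "frames_retained": n_retained,
    }
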