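"""Incident frames, matched references, exclusions and pairing."""

from datetime import datetime
from zoneinfo import ZoneInfo

import numpy as np
import pytest

from e4arousal.frames import (
    AnalysisFrame,
    FrameConfig,
    build_reference_frames,
    exclusion_summary,
    extract_incident_frames,
    filter_artifact_frames,
    frame_ledger,
    summarize_frame,
)
from e4arousal.observations import ObservationEvent, ObservationLog
from e4arousal.pipeline import analyze_days, process_session
from conftest import T0, build_session

DAY_S = 86400.0
DUR = 7200.0  # two recorded hours per day


def make_week(eda_by_day=None, hr_by_day=None, pid="P01", n_days=5):
    """Five processed 2-hour days starting 08:00 local on consecutive dates."""
    days = {}
    for d in range(1, n_days + 1):
        start = T0 + (d - 1) * DAY_S
        session = build_session(
            DUR,
            start=start,
            eda=(eda_by_day or {}).get(d),
            hr=(hr_by_day or {}).get(d),
            participant_id=pid,
            day_index=d,
        )
        days[(pid, d)] = process_session(session)
    return days


def red(t, pid="P01"):
    return ObservationEvent(pid, t, "red", "hitting", "staff")


def orange(t, pid="P01"):
    return ObservationEvent(pid, t, "orange", "shouting", "staff")


EVENT_T = T0 + 2 * DAY_S + 3600.0  # day 3, 09:00 local


class TestIncidentExtraction:
    def test_red_event_anchors_a_frame_at_its_recorded_time(self):
        days = make_week()
        frames = extract_incident_frames(ObservationLog([red(EVENT_T)]), days)
        (f,) = frames
        assert f.start == EVENT_T and f.day_index == 3 and f.usable
        assert f.end - f.start == 300.0

    def test_event_outside_wearing_hours_is_missing_data(self):
        days = make_week()
        night = T0 + 2 * DAY_S + 12 * 3600.0
        frames = extract_incident_frames(ObservationLog([red(night)]), days)
        (f,) = frames
        assert f.exclusion_reason == "missing_data"

    def test_orange_events_do_not_anchor_incidents(self):
        days = make_week()
        assert extract_incident_frames(ObservationLog([orange(EVENT_T)]), days) == []

    def test_reds_within_five_minutes_merge_to_earliest(self):
        days = make_week()
        frames = extract_incident_frames(
            ObservationLog([red(EVENT_T), red(EVENT_T + 180.0)]), days
        )
        assert len(frames) == 1 and frames[0].start == EVENT_T


class TestReferenceFrames:
    def run(self, log_events, n_days=5):
        days = make_week(n_days=n_days)
        log = ObservationLog(log_events)
        frames = extract_incident_frames(log, days)
        incident = next(f for f in frames if f.start == log_events[0].timestamp)
        return build_reference_frames(incident, days, log)

    def test_four_other_days_give_four_references(self):
        ps = self.run([red(EVENT_T)])
        assert len(ps.references) == 4 and not ps.excluded_references

    def test_reference_matches_incident_clock_time_to_the_second(self):
        ps = self.run([red(EVENT_T)])
        tz = ZoneInfo("Europe/Amsterdam")
        inc_clock = datetime.fromtimestamp(ps.incident.start, tz).time()
        for r in ps.references:
            assert datetime.fromtimestamp(r.start, tz).time() == inc_clock
            assert r.day_index != ps.incident.day_index

    def test_red_on_reference_day_excludes_it(self):
        ps = self.run([red(EVENT_T), red(T0 + DAY_S + 3600.0 + 120.0)])  # day 2, 09:02
        assert len(ps.references) == 3
        (exc,) = ps.excluded_references
        assert exc.exclusion_reason == "aggression_overlap" and exc.day_index == 2

    def test_orange_overlap_also_excludes_by_default(self):
        ps = self.run([red(EVENT_T), orange(T0 + 3600.0 + 240.0)])  # day 1, 09:04
        assert any(e.exclusion_reason == "aggression_overlap" for e in ps.excluded_references)

    def test_red_only_exclusion_is_configurable(self):
        days = make_week()
        log = ObservationLog([red(EVENT_T), orange(T0 + 3600.0 + 240.0)])
        (incident,) = extract_incident_frames(log, days)
        cfg = FrameConfig(aggression_colors=("red",))
        ps = build_reference_frames(incident, days, log, cfg)
        assert len(ps.references) == 4

    def test_event_uncertainty_widens_the_overlap_test(self):
        # event 30 s before the reference window still overlaps via ±60 s width
        ps = self.run([red(EVENT_T), orange(T0 + DAY_S + 3600.0 - 30.0)])
        assert any(e.day_index == 2 for e in ps.excluded_references)

    def test_single_day_participant_has_no_candidates(self):
        ps = self.run([red(T0 + 3600.0)], n_days=1)
        assert ps.candidate_count() == 0 and not ps.usable


class TestArtifactFilter:
    def frame(self, frac):
        return AnalysisFrame("P01", "reference", T0, 1, artifact_fraction=frac)

    def test_boundary_exactly_at_threshold_is_retained(self):
        retained, excluded = filter_artifact_frames([self.frame(0.75)], 0.75)
        assert len(retained) == 1 and not excluded

    def test_just_above_threshold_is_excluded(self):
        retained, excluded = filter_artifact_frames([self.frame(0.75 + 1e-9)], 0.75)
        assert not retained and excluded[0].exclusion_reason == "artifact_gt_75"

    def test_clean_frame_is_retained(self):
        retained, _ = filter_artifact_frames([self.frame(0.0)], 0.75)
        assert len(retained) == 1


class TestSummaries:
    def test_constant_hr_means_95(self):
        days = make_week()
        s = summarize_frame(days[("P01", 3)], EVENT_T, EVENT_T + 300.0)
        assert s["hr_bpm"] == pytest.approx(95.0)
        assert s["scl_uS"] == pytest.approx(2.0)

    def test_half_off_wrist_hr_averages_remaining_half(self):
        # first 150 s of the window carry an invalidated (off-wrist) HR
        eda = np.full(int(DUR * 4), 2.0)
        w0 = int((EVENT_T - (T0 + 2 * DAY_S)) * 4)
        eda[: w0 + 150 * 4] = 0.0  # off-wrist from day start into half the window
        hr = np.full(int(DUR), 95.0)
        hr[: w0 // 4 + 150] = 160.0  # artificially high while off wrist
        days = make_week(eda_by_day={3: eda}, hr_by_day={3: hr})
        s = summarize_frame(days[("P01", 3)], EVENT_T, EVENT_T + 300.0)
        assert s["hr_bpm"] == pytest.approx(95.0)

    def test_fully_off_wrist_window_has_all_summaries_missing(self):
        eda = np.zeros(int(DUR * 4))
        hr = np.full(int(DUR), 160.0)
        days = make_week(eda_by_day={3: eda}, hr_by_day={3: hr})
        s = summarize_frame(days[("P01", 3)], EVENT_T, EVENT_T + 300.0)
        assert all(np.isnan(v) for v in s.values())


class TestPairingAndAccounting:
    def test_injected_hr_effect_is_recovered_exactly(self):
        hr = np.full(int(DUR), 95.0)
        w0 = int(EVENT_T - (T0 + 2 * DAY_S))
        hr[w0 : w0 + 300] += 9.0
        days = make_week(hr_by_day={3: hr})
        log = ObservationLog([red(EVENT_T)])
        result = analyze_days(days, log)
        tab = result.tables["hr_bpm"]
        assert len(tab) == 1
        assert tab["incident"][0] - tab["reference"][0] == pytest.approx(9.0)

    def test_accounting_conserves_counts(self):
        days = make_week()
        log = ObservationLog(
            [red(EVENT_T), red(T0 + DAY_S + 3600.0), orange(T0 + 3 * DAY_S + 3600.0)]
        )
        result = analyze_days(days, log)
        ex = result.exclusions
        ledger = result.ledger()
        assert ex["frames_total"] == len(ledger)
        n_accounted = (
            ex["frames_retained"]
            + ex["frames_excluded_artifact"]
            + ex["frames_excluded_missing"]
            + ex["reference_excluded_aggression"]
        )
        assert n_accounted == ex["frames_total"]

    def test_measure_missing_on_one_side_drops_that_measure_only(self):
        hr = np.full(int(DUR), np.nan)  # no HR on the incident day
        days = make_week(hr_by_day={3: hr})
        log = ObservationLog([red(EVENT_T)])
        result = analyze_days(days, log)
        assert len(result.tables["hr_bpm"]) == 0
        assert len(result.tables["scl_uS"]) == 1

    def test_references_never_on_the_incident_day(self):
        days = make_week()
        log = ObservationLog([red(EVENT_T)])
        result = analyze_days(days, log)
        for ps in result.paired_sets:
            for r in ps.references + ps.excluded_references:
                assert r.day_index != ps.incident.day_index


class TestExclusionArithmetic:
    def test_study_scale_percentages_from_constructed_ledger(self):
        # 192 candidate references of which 35 overlap aggression -> 18.2%;
        # 1723 frames of which 354 fail the artifact filter -> 20.5%
        from conftest import build_study_scale_paired_sets

        summary = exclusion_summary(build_study_scale_paired_sets())
        assert summary["reference_candidates"] == 192
        assert summary["reference_excluded_aggression"] == 35
        assert summary["reference_excluded_aggression_pct"] == 18.2
        assert summary["frames_total"] == 1723
        assert summary["frames_excluded_artifact"] == 354
        assert summary["frames_excluded_artifact_pct"] == 20.5
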