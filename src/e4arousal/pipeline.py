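"""End-to-end orchestration: sessions → masks → features → frames → tests.

`process_session` turns one raw session into a :class:`~e4arousal.frames.ProcessedDay`
(quality mask with off-wrist labeling, invalidated HR, movement, SCL, SCR
peaks).  `analyze_days` runs the incident/reference frame procedure and the
Bonferroni-corrected paired family on a set of processed days plus an
observation log.  `run_cohort_analysis` does the whole thing on a synthetic
cohort, streaming day by day so large cohorts never sit in memory whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .e4io import E4Session, SignalChannel
from .features import FeatureConfig, detect_scr_peaks, movement_magnitude, smooth_eda
from .frames import (
    FrameConfig,
    PairedFrameSet,
    ProcessedDay,
    assemble_pairs,
    build_reference_frames,
    exclusion_summary,
    extract_incident_frames,
    filter_artifact_frames,
    frame_ledger,
)
from .observations import ObservationLog
from .quality import (
    QualityConfig,
    QualityMask,
    classify_eda_epochs,
    detect_off_wrist,
    invalidate_hr_off_wrist,
    retention_report,
)
from .stats import PairedComparisonResult, family_table, run_family
from .synth import SyntheticConfig, iter_cohort_days

__all__ = [
    "PipelineConfig",
    "process_session",
    "analyze_days",
    "run_cohort_analysis",
    "AnalysisResult",
    "CohortResult",
]


@dataclass
class PipelineConfig:
    quality: QualityConfig = field(default_factory=QualityConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    frames: FrameConfig = field(default_factory=FrameConfig)
    family_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        cfg = cls()
        for section, target in (
            ("quality", cfg.quality),
            ("features", cfg.features),
            ("frames", cfg.frames),
        ):
            for k, v in (raw.get(section) or {}).items():
                if not hasattr(target, k):
                    raise ValueError(f"unknown config key {section}.{k}")
                setattr(target, k, tuple(v) if isinstance(v, list) else v)
        cfg.family_alpha = raw.get("family_alpha", cfg.family_alpha)
        return cfg


def process_session(
    session: E4Session, config: PipelineConfig | None = None, compact: bool = False
) -> ProcessedDay:
    """Quality-mask and feature-derive one session.

    ``compact=True`` drops the bulk raw channels (ACC/BVP/TEMP samples) after
    they have been consumed, which keeps multi-hundred-day cohort analyses
    small; dashboards should keep the full session.
    """
    cfg = config or PipelineConfig()
    eda, temp = session["EDA"], session["TEMP"]
    mask = classify_eda_epochs(eda, temp, epoch_length=cfg.quality.epoch_s, config=cfg.quality)
    mask = detect_off_wrist(mask, cfg.quality.long_noise_s)
    hr = invalidate_hr_off_wrist(session["HR"], mask)
    movement = movement_magnitude(
        session["ACC_X"],
        session["ACC_Y"],
        session["ACC_Z"],
        median_window_s=cfg.features.movement_median_s,
        out_rate=1.0,
    )
    scl = smooth_eda(eda, mask, cfg.features.scl_window_s)
    peaks = detect_scr_peaks(
        eda,
        mask,
        min_amplitude=cfg.features.scr_min_amp_uS,
        min_rise=cfg.features.scr_min_rise_s,
        min_separation=cfg.features.scr_min_separation_s,
        scl_window_s=cfg.features.scl_window_s,
        presmooth_s=cfg.features.scr_presmooth_s,
    )
    if compact:
        slim = dict(session.channels)
        for name in ("ACC_X", "ACC_Y", "ACC_Z", "BVP", "TEMP"):
            ch = slim[name]
            slim[name] = SignalChannel(name, ch.start_time, ch.rate, np.empty(0))
        session = replace(session, channels=slim)
    return ProcessedDay(session=session, mask=mask, hr=hr, movement=movement, scl=scl, peaks=peaks)


@dataclass
class AnalysisResult:
    paired_sets: list[PairedFrameSet]
    tables: dict[str, pd.DataFrame]
    results: list[PairedComparisonResult]
    exclusions: dict

    def ledger(self) -> pd.DataFrame:
        return frame_ledger(self.paired_sets)

    def table(self) -> pd.DataFrame:
        return family_table(self.results)


def analyze_days(
    days: dict[tuple[str, int], ProcessedDay],
    log: ObservationLog,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """The core procedure: incident frames, matched references, paired family."""
    cfg = config or PipelineConfig()
    incidents = extract_incident_frames(log, days, cfg.frames)
    # the artifact filter applies to incident frames exactly as to references
    filter_artifact_frames(
        [f for f in incidents if f.usable], cfg.frames.artifact_threshold
    )
    paired_sets = [
        build_reference_frames(f, days, log, cfg.frames) if f.usable else PairedFrameSet(f)
        for f in incidents
    ]
    tables = assemble_pairs(paired_sets)
    results = run_family(tables, cfg.family_alpha)
    return AnalysisResult(paired_sets, tables, results, exclusion_summary(paired_sets))


@dataclass
class CohortResult:
    analysis: AnalysisResult
    retention: pd.DataFrame
    truths: list[dict]
    log: ObservationLog

    def mean_paired_difference(self, measure: str) -> tuple[float, float, int]:
        """(mean difference, standard error, n) for one measure's pairs."""
        tab = self.analysis.tables[measure]
        d = tab["incident"].to_numpy() - tab["reference"].to_numpy()
        return float(d.mean()), float(d.std(ddof=1) / np.sqrt(len(d))), len(d)


def run_cohort_analysis(
    synth_config: SyntheticConfig,
    seed: int,
    config: PipelineConfig | None = None,
) -> CohortResult:
    """Generate a synthetic cohort and push it through the full pipeline."""
    cfg = config or PipelineConfig()
    days: dict[tuple[str, int], ProcessedDay] = {}
    events, truths = [], []
    masks: list[QualityMask] = []
    sessions: list[E4Session] = []
    for p, session, evs, truth in iter_cohort_days(synth_config, seed):
        day = process_session(session, cfg, compact=True)
        days[(p.participant_id, session.day_index)] = day
        masks.append(day.mask)
        sessions.append(day.session)
        events.extend(evs)
        truths.append(truth)
    log = ObservationLog(events)
    analysis = analyze_days(days, log, cfg)
    return CohortResult(analysis, retention_report(masks, sessions), truths, log)
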