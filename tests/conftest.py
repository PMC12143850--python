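"""Shared fixtures: programmatically built sessions, masks and logs."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from e4arousal.e4io import E4Session, IbiSeries, SignalChannel
from e4arousal.quality import QualityConfig, classify_eda_epochs, detect_off_wrist

#: 2023-03-06 08:00 Europe/Amsterdam (CET, UTC+1) as UTC seconds
T0 = datetime(2023, 3, 6, 7, 0, tzinfo=timezone.utc).timestamp()


def build_session(
    duration_s: float = 600.0,
    start: float = T0,
    eda: np.ndarray | None = None,
    temp: np.ndarray | None = None,
    hr: np.ndarray | None = None,
    acc: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    ibi: IbiSeries | None = None,
    participant_id: str = "P01",
    setting: str = "clinic",
    day_index: int = 1,
    timezone_name: str = "Europe/Amsterdam",
) -> E4Session:
    """A session with constant, physiologically unremarkable defaults."""
    n4, n1, n32, n64 = (int(duration_s * r) for r in (4, 1, 32, 64))
    if eda is None:
        eda = np.full(n4, 2.0)
    if temp is None:
        temp = np.full(len(eda), 33.0)
    if hr is None:
        hr = np.full(n1, 95.0)
    if acc is None:
        acc = (np.zeros(n32), np.zeros(n32), np.ones(n32))
    channels = {
        "EDA": SignalChannel("EDA", start, 4.0, eda),
        "TEMP": SignalChannel("TEMP", start, 4.0, temp),
        "ACC_X": SignalChannel("ACC_X", start, 32.0, acc[0]),
        "ACC_Y": SignalChannel("ACC_Y", start, 32.0, acc[1]),
        "ACC_Z": SignalChannel("ACC_Z", start, 32.0, acc[2]),
        "BVP": SignalChannel("BVP", start, 64.0, np.zeros(n64)),
        "HR": SignalChannel("HR", start, 1.0, hr),
    }
    return E4Session(
        participant_id, setting, day_index, channels, ibi or IbiSeries(start), timezone_name
    )


def masked(session: E4Session, long_noise_s: float = 600.0):
    mask = classify_eda_epochs(session["EDA"], session["TEMP"], config=QualityConfig())
    return detect_off_wrist(mask, long_noise_s)


@pytest.fixture
def quiet_session() -> E4Session:
    """10 minutes of clean constant signal."""
    return build_session()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230306)


def build_retention_mask(raw_h: float, off_h: float, artifact_h: float):
    """A quality mask whose cleaning-stage hours are exactly as requested."""
    from e4arousal.quality import ARTIFACT, OFF_WRIST, VALID, QualityMask

    n_raw = round(raw_h * 720)  # 5 s epochs
    n_off = round(off_h * 720)
    n_art = round(artifact_h * 720)
    labels = np.array(
        [OFF_WRIST] * n_off + [ARTIFACT] * n_art + [VALID] * (n_raw - n_off - n_art),
        dtype=object,
    )
    return QualityMask("EDA", T0, 5.0, labels, [()] * n_raw, 5.0 * n_raw)


def build_study_scale_paired_sets():
    """Frame sets matching the study's exclusion bookkeeping exactly:
    192 candidate references with 35 aggression overlaps, and 1723 frames in
    total with 354 failing the artifact filter."""
    from e4arousal.frames import AnalysisFrame, PairedFrameSet, filter_artifact_frames

    sets = []
    agg_left = 35
    for i in range(192 // 4):
        inc = AnalysisFrame("P01", "incident", T0 + i * 400.0, 1, artifact_fraction=0.0)
        ps = PairedFrameSet(inc)
        for j in range(4):
            f = AnalysisFrame(
                "P01", "reference", T0 + i * 400.0, 2 + j, artifact_fraction=0.0
            )
            if agg_left > 0:
                f.exclusion_reason = "aggression_overlap"
                agg_left -= 1
                ps.excluded_references.append(f)
            else:
                ps.references.append(f)
        sets.append(ps)
    # 48 incidents + 192 references so far; pad to the study-scale frame total
    for i in range(1723 - 240):
        inc = AnalysisFrame(
            "P02",
            "incident",
            T0 + i * 400.0,
            1,
            artifact_fraction=0.9 if i < 354 else 0.0,
        )
        sets.append(PairedFrameSet(inc))
    for ps in sets:
        filter_artifact_frames([ps.incident], 0.75)
    return sets
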