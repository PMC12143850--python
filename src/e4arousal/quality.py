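"""Epoch-level signal-quality classification for wrist EDA.

Electrodermal data from ambulatory wearables carries two kinds of unusable
signal that must be told apart for retention accounting: short in-signal
*artifacts* (pressure/motion transients, electrode lift) and *long noise* —
runs of at least ~10 minutes without valid data, where the watch was most
likely not on the wrist at all.  Off-wrist spans matter beyond EDA because the
device keeps emitting an (artificially high) heart rate even when unworn, so
off-wrist status must be propagated to HR.

Classification is rule-based on fixed-length epochs (default 5 s):

* range rule   — EDA below a floor (near-zero conductance means no skin
                 contact) or above a ceiling;
* slope rule   — absolute EDA slope above the maximum physiological rate;
* temperature  — skin temperature below the skin-contact floor.

The rules and thresholds are deliberately simple, transparent and individually
configurable; no learned artifact classifier is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .e4io import E4Session, SignalChannel

__all__ = [
    "VALID",
    "ARTIFACT",
    "OFF_WRIST",
    "QualityConfig",
    "QualityMask",
    "classify_eda_epochs",
    "detect_off_wrist",
    "invalidate_hr_off_wrist",
    "retention_report",
    "retention_percent",
]

VALID = "valid"
ARTIFACT = "artifact"
OFF_WRIST = "off_wrist"


@dataclass
class QualityConfig:
    """Thresholds for the epoch rules; see module docstring for rationale."""

    epoch_s: float = 5.0
    eda_floor_uS: float = 0.05
    eda_ceiling_uS: float = 60.0
    max_slope_uS_per_s: float = 10.0
    temp_floor_C: float = 30.0
    long_noise_s: float = 600.0


@dataclass
class QualityMask:
    """Epoch labels over one channel's full duration.

    ``labels[i]`` covers ``[start_time + i*epoch_length, ... + epoch_length)``
    except the last epoch, which may be partial.  ``provenance[i]`` lists the
    rule identifiers that fired for that epoch.
    """

    channel: str
    start_time: float
    epoch_length: float
    labels: np.ndarray  # dtype object, values in {valid, artifact, off_wrist}
    provenance: list[tuple[str, ...]]
    duration: float  # seconds of signal covered

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.provenance):
            raise ValueError("labels and provenance must align")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def epoch_durations(self) -> np.ndarray:
        """Seconds covered by each epoch (last one may be partial)."""
        d = np.full(self.n_epochs, self.epoch_length)
        if self.n_epochs:
            d[-1] = self.duration - self.epoch_length * (self.n_epochs - 1)
        return d

    def epoch_starts(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_epochs) * self.epoch_length

    def labels_at(self, times: np.ndarray) -> np.ndarray:
        """Epoch label at each timestamp; outside the mask → ``artifact``."""
        times = np.asarray(times, dtype=float)
        idx = np.floor((times - self.start_time) / self.epoch_length).astype(int)
        out = np.full(times.shape, ARTIFACT, dtype=object)
        inside = (times >= self.start_time) & (times < self.start_time + self.duration)
        out[inside] = self.labels[np.clip(idx[inside], 0, self.n_epochs - 1)]
        return out

    def spans(self, label: str) -> list[tuple[float, float]]:
        """Maximal [start, end) wall-clock spans carrying ``label``."""
        out: list[tuple[float, float]] = []
        starts = self.epoch_starts()
        durs = self.epoch_durations()
        run_start = None
        for i in range(self.n_epochs):
            if self.labels[i] == label and run_start is None:
                run_start = starts[i]
            if self.labels[i] != label and run_start is not None:
                out.append((run_start, starts[i]))
                run_start = None
        if run_start is not None:
            out.append((run_start, starts[-1] + durs[-1]))
        return out

    def seconds_with(self, *labels: str) -> float:
        durs = self.epoch_durations()
        sel = np.isin(self.labels.astype(str), labels)
        return float(durs[sel].sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: epoch_start_utc, epoch_end_utc, label, rules_fired."""
        starts = self.epoch_starts()
        return pd.DataFrame(
            {
                "epoch_start_utc": starts,
                "epoch_end_utc": starts + self.epoch_durations(),
                "label": self.labels.astype(str),
                "rules_fired": ["|".join(p) for p in self.provenance],
            }
        )


def _epoch_reduce(flags: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """OR of per-sample booleans within each epoch."""
    return np.maximum.reduceat(flags.astype(np.int8), edges).astype(bool)


def classify_eda_epochs(
    eda: SignalChannel,
    temp: SignalChannel | None = None,
    acc_magnitude=None,  # accepted for interface symmetry; no default rule uses it
    epoch_length: float | None = None,
    config: QualityConfig | None = None,
) -> QualityMask:
    """Label every epoch of an EDA channel valid/artifact by the three rules.

    An epoch is *artifact* as soon as any rule fires anywhere inside it:
    range (floor/ceiling), slope, or skin-temperature floor.  Missing (NaN)
    samples fire a dedicated ``missing`` rule.  With no temperature channel
    the temperature rule is skipped with a warning.
    """
    cfg = config or QualityConfig()
    ep = epoch_length if epoch_length is not None else cfg.epoch_s
    n = len(eda)
    if n == 0:
        return QualityMask(eda.name, eda.start_time, ep, np.empty(0, dtype=object), [], 0.0)

    spe = max(int(round(ep * eda.rate)), 1)  # samples per epoch
    edges = np.arange(0, n, spe)
    v = eda.values

    fired: dict[str, np.ndarray] = {}
    with np.errstate(invalid="ignore"):
        fired["eda_floor"] = _epoch_reduce(v < cfg.eda_floor_uS, edges)
        fired["eda_ceiling"] = _epoch_reduce(v > cfg.eda_ceiling_uS, edges)
        slope = np.abs(np.diff(v)) * eda.rate
        # a boundary-crossing step is attributed to the epoch of its left sample
        fired["eda_slope"] = _epoch_reduce(
            np.append(slope > cfg.max_slope_uS_per_s, False), edges
        )
    fired["missing"] = _epoch_reduce(~np.isfinite(v), edges)

    if temp is not None and len(temp):
        tmean = _epoch_mean_by_time(temp, eda.start_time, ep, len(edges))
        with np.errstate(invalid="ignore"):
            fired["temp_floor"] = np.nan_to_num(tmean, nan=np.inf) < cfg.temp_floor_C
    else:
        warnings.warn("no temperature channel; skin-temperature rule skipped")

    any_fired = np.logical_or.reduce(list(fired.values()))
    labels = np.where(any_fired, ARTIFACT, VALID).astype(object)
    rule_names = list(fired)
    provenance = [
        tuple(r for r in rule_names if fired[r][i]) for i in range(len(edges))
    ]
    return QualityMask(eda.name, eda.start_time, ep, labels, provenance, eda.duration)


def _epoch_mean_by_time(
    ch: SignalChannel, start: float, epoch_length: float, n_epochs: int
) -> np.ndarray:
    t = ch.times()
    idx = np.floor((t - start) / epoch_length).astype(int)
    ok = (idx >= 0) & (idx < n_epochs) & np.isfinite(ch.values)
    sums = np.bincount(idx[ok], weights=ch.values[ok], minlength=n_epochs)
    cnts = np.bincount(idx[ok], minlength=n_epochs)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)


def detect_off_wrist(mask: QualityMask, long_noise_threshold: float = 600.0) -> QualityMask:
    """Relabel long runs of invalid epochs as off-wrist.

    A maximal run of consecutive non-valid epochs whose total duration reaches
    ``long_noise_threshold`` (default 10 min) becomes ``off_wrist``; shorter
    runs stay ``artifact``.  Valid epochs are never touched, and the operation
    is idempotent.
    """
    labels = mask.labels.copy()
    prov = [tuple(p) for p in mask.provenance]
    durs = mask.epoch_durations()
    invalid = labels != VALID
    i = 0
    n = len(labels)
    while i < n:
        if not invalid[i]:
            i += 1
            continue
        j = i
        while j < n and invalid[j]:
            j += 1
        if durs[i:j].sum() >= long_noise_threshold:
            for k in range(i, j):
                if labels[k] != OFF_WRIST:
                    labels[k] = OFF_WRIST
                    prov[k] = prov[k] + ("long_noise",)
        i = j
    return QualityMask(mask.channel, mask.start_time, mask.epoch_length, labels, prov, mask.duration)


def invalidate_hr_off_wrist(hr: SignalChannel, mask: QualityMask) -> SignalChannel:
    """Blank device HR inside off-wrist spans.

    The device derives HR even when unworn, producing plausible-looking but
    artificially high values; those samples are replaced by NaN.  Everything
    else is returned unchanged.
    """
    values = hr.values.copy()
    t = hr.times()
    for s, e in mask.spans(OFF_WRIST):
        values[(t >= s) & (t < e)] = np.nan
    return SignalChannel(hr.name, hr.start_time, hr.rate, values)


def retention_percent(before_h: float, after_h: float) -> int:
    """Signed integer percent change from one retention stage to the next."""
    if before_h == 0:
        return 0
    return int(round((after_h - before_h) / before_h * 100))


def retention_report(masks, sessions) -> pd.DataFrame:
    """Per-participant (and mean) EDA hours through the cleaning stages.

    Stages: raw recorded hours → hours after removing long noise (off-wrist)
    → hours after also removing artifacts, with the percent change relative to
    the preceding stage rounded to integer (the convention used for cohort
    retention accounting).
    """
    rows: dict[str, dict[str, float]] = {}
    for mask, session in zip(masks, sessions):
        pid = session.participant_id
        r = rows.setdefault(pid, {"raw_h": 0.0, "after_long_noise_h": 0.0, "after_artifact_h": 0.0})
        raw = mask.duration
        off = mask.seconds_with(OFF_WRIST)
        art = mask.seconds_with(ARTIFACT)
        r["raw_h"] += raw / 3600.0
        r["after_long_noise_h"] += (raw - off) / 3600.0
        r["after_artifact_h"] += (raw - off - art) / 3600.0

    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.loc["mean"] = df.mean()
    df["long_noise_pct"] = [
        retention_percent(a, b) for a, b in zip(df["raw_h"], df["after_long_noise_h"])
    ]
    df["artifact_pct"] = [
        retention_percent(a, b)
        for a, b in zip(df["after_long_noise_h"], df["after_artifact_h"])
    ]
    df.index.name = "participant_id"
    return df
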