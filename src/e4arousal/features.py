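"""Derived arousal measures from masked raw signals.

The dashboard and analysis measures are:

* movement (g)      — magnitude of gravity-removed acceleration;
* SCL (µS)          — tonic skin conductance level, operationalized as a
                      centered moving average of the raw EDA signal;
* SCR peaks / PPM   — phasic skin-conductance responses counted per minute of
                      valid signal (nonspecific sympathetic responding);
* HR (bpm)          — device-derived, off-wrist-invalidated upstream;
* HRV RMSSD (ms)    — root mean square of successive inter-beat-interval
                      differences, computed only from beats the device marked
                      consecutive, and reported missing when too few such
                      pairs exist (on this device, valid IBI covers only a
                      small fraction of wear time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .e4io import IbiSeries, SignalChannel
from .quality import QualityMask, VALID

__all__ = [
    "FeatureConfig",
    "DerivedSeries",
    "ScrPeak",
    "movement_magnitude",
    "smooth_eda",
    "detect_scr_peaks",
    "peaks_per_minute",
    "rmssd",
]

MEASURES = ("movement_g", "scl_uS", "ppm", "hr_bpm", "hrv_rmssd_ms", "temp_C")


@dataclass
class FeatureConfig:
    scl_window_s: float = 30.0
    scr_min_amp_uS: float = 0.05
    scr_min_rise_s: float = 0.25
    scr_min_separation_s: float = 1.0
    scr_presmooth_s: float = 0.5
    rmssd_min_beats: int = 10
    movement_median_s: float = 60.0
    ppm_denominator: str = "valid"  # "valid" | "wall"


@dataclass
class DerivedSeries:
    """A derived measure on a regular grid; NaN marks missing."""

    measure: str
    start_time: float
    rate: float
    values: np.ndarray
    window: float = 0.0  # smoothing/aggregation window, seconds

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.rate

    def window_mean(self, start: float, end: float) -> float:
        """NaN-aware mean of samples with time in [start, end); NaN if none."""
        i0 = int(np.ceil((start - self.start_time) * self.rate - 1e-9))
        i1 = int(np.ceil((end - self.start_time) * self.rate - 1e-9))
        seg = self.values[max(i0, 0) : max(min(i1, len(self.values)), 0)]
        if len(seg) == 0 or not np.isfinite(seg).any():
            return float("nan")
        return float(np.nanmean(seg))


@dataclass
class ScrPeak:
    """One skin-conductance response: onset (preceding trough) to peak."""

    onset_time: float
    peak_time: float
    amplitude: float  # µS, peak minus onset on the phasic component

    def __post_init__(self) -> None:
        if self.peak_time <= self.onset_time:
            raise ValueError("peak must follow onset")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


# ---------------------------------------------------------------------------
# movement


def _block_median_baseline(values: np.ndarray, block: int) -> np.ndarray:
    """Slow baseline: medians of non-overlapping blocks, linearly interpolated.

    Exact for constant signals and for zero-mean oscillations spanning full
    periods inside a block — the two regimes that matter for static-gravity
    estimation — at O(n log block) cost.
    """
    n = len(values)
    if n == 0:
        return values.copy()
    nblocks = max(n // block, 1)
    used = nblocks * block
    med = np.median(values[:used].reshape(nblocks, block), axis=1)
    centers = (np.arange(nblocks) + 0.5) * block
    return np.interp(np.arange(n), centers, med)


def movement_magnitude(
    acc_x: SignalChannel,
    acc_y: SignalChannel,
    acc_z: SignalChannel,
    median_window_s: float = 60.0,
    out_rate: float = 1.0,
) -> DerivedSeries:
    """Gravity-removed acceleration magnitude, aggregated to the analysis grid.

    The static (gravity) component is estimated per axis by a moving median of
    window ``median_window_s`` and subtracted; the Euclidean norm of the
    residual is the instantaneous movement, averaged into ``out_rate`` bins.
    A device at rest in any orientation yields ≈0 g.
    """
    axes = (acc_x, acc_y, acc_z)
    if len({len(a) for a in axes}) != 1 or len({a.rate for a in axes}) != 1:
        raise ValueError("accelerometer axes must share length and rate")
    if len({a.start_time for a in axes}) != 1:
        raise ValueError("accelerometer axes must share the start time")
    rate = acc_x.rate
    block = max(int(round(median_window_s * rate)), 1)
    dyn = [a.values - _block_median_baseline(a.values, block) for a in axes]
    mag = np.sqrt(dyn[0] ** 2 + dyn[1] ** 2 + dyn[2] ** 2)
    factor = max(int(round(rate / out_rate)), 1)
    from .e4io import bin_mean

    return DerivedSeries(
        "movement_g", acc_x.start_time, rate / factor, bin_mean(mag, factor), median_window_s
    )


# ---------------------------------------------------------------------------
# EDA: tonic level and phasic peaks


def _centered_window_sum(v: np.ndarray, w: int) -> np.ndarray:
    """Sum over the window [i-(w-1)//2, i+w//2], truncated at the edges."""
    n = len(v)
    cs = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.clip(np.arange(n) - (w - 1) // 2, 0, n)
    hi = np.clip(np.arange(n) + w // 2 + 1, 0, n)
    return cs[hi] - cs[lo]


def _sample_valid(eda: SignalChannel, mask: QualityMask | None) -> np.ndarray:
    valid = np.isfinite(eda.values)
    if mask is not None:
        valid &= mask.labels_at(eda.times()) == VALID
    return valid


def smooth_eda(
    eda: SignalChannel,
    mask: QualityMask | None = None,
    window_s: float = 30.0,
    mask_output: bool = True,
) -> DerivedSeries:
    """Tonic skin conductance level: centered moving average over valid samples.

    Samples in artifact/off-wrist epochs are excluded from every window mean;
    a window with no valid samples yields NaN.  With ``mask_output`` (the
    analysis contract) the output is additionally forced missing wherever the
    source epoch itself is invalid; ``mask_output=False`` keeps the
    interpolating estimate, which the peak detector uses as its tonic
    baseline.
    """
    w = max(int(round(window_s * eda.rate)), 1)
    valid = _sample_valid(eda, mask)
    vals = np.where(valid, eda.values, 0.0)
    sums = _centered_window_sum(vals, w)
    cnts = _centered_window_sum(valid.astype(float), w)
    with np.errstate(invalid="ignore", divide="ignore"):
        scl = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    if mask_output:
        scl = np.where(
            (mask.labels_at(eda.times()) == VALID) if mask is not None else np.isfinite(eda.values),
            scl,
            np.nan,
        )
    return DerivedSeries("scl_uS", eda.start_time, eda.rate, scl, window_s)


def detect_scr_peaks(
    eda: SignalChannel,
    mask: QualityMask | None = None,
    min_amplitude: float = 0.05,
    min_rise: float = 0.25,
    min_separation: float = 1.0,
    scl_window_s: float = 30.0,
    max_rise_s: float = 5.0,
    presmooth_s: float = 0.5,
) -> list[ScrPeak]:
    """Trough-to-peak SCR detection on the phasic component (raw − SCL).

    The phasic signal is lightly low-pass filtered (``presmooth_s`` moving
    average) before peak picking so that sensor-noise extrema cannot reach
    the amplitude criterion; a skin-conductance response is an order of
    magnitude slower than the noise.  Local maxima then qualify when the rise
    from the preceding trough is at least ``min_amplitude`` µS over a rise
    time between ``min_rise`` and ``max_rise_s`` seconds — the upper bound
    rejects slow baseline rebounds of the moving-average tonic estimate,
    which are not skin-conductance responses.  Peaks inside artifact or
    off-wrist epochs are discarded.
    """
    if len(eda) == 0:
        return []
    scl = smooth_eda(eda, mask, scl_window_s, mask_output=False).values
    phasic = np.nan_to_num(eda.values - scl)
    ps = int(round(presmooth_s * eda.rate))
    if ps > 1:
        from scipy.ndimage import uniform_filter1d

        phasic = uniform_filter1d(phasic, ps)
    distance = max(int(round(min_separation * eda.rate)), 1)
    # prominence pre-filter rejects noise maxima riding on a response's decay
    idx, _ = find_peaks(phasic, distance=distance, prominence=min_amplitude)
    labels = mask.labels_at(eda.times()) if mask is not None else None
    t = eda.times()
    lookback = max(int(round(max_rise_s * eda.rate)), 1)

    peaks: list[ScrPeak] = []
    for p in idx:
        if labels is not None and labels[p] != VALID:
            continue
        # trough = minimum within the admissible rise window before the peak
        # (robust to single-sample noise dips on the rising limb)
        lo = max(p - lookback, 0)
        q = lo + int(np.argmin(phasic[lo:p])) if p > lo else p
        amp = phasic[p] - phasic[q]
        rise = (p - q) / eda.rate
        if amp >= min_amplitude and min_rise <= rise <= max_rise_s:
            peaks.append(ScrPeak(onset_time=t[q], peak_time=t[p], amplitude=float(amp)))
    return peaks


def peaks_per_minute(
    peaks,
    window_start: float,
    window_end: float,
    valid_fraction: float = 1.0,
) -> float:
    """SCR peak count per minute of valid signal in [window_start, window_end).

    ``valid_fraction`` is the non-artifact share of the window; with the
    ``wall`` denominator convention callers pass 1.0.  Zero valid minutes
    yields NaN rather than a spurious 0.
    """
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    valid_min = (window_end - window_start) / 60.0 * valid_fraction
    if valid_min <= 0:
        return float("nan")
    count = sum(1 for p in peaks if window_start <= p.peak_time < window_end)
    return count / valid_min


# ---------------------------------------------------------------------------
# HRV


def rmssd(
    ibi: IbiSeries,
    window_start: float,
    window_end: float,
    min_beats: int = 10,
    gap_tol_s: float = 0.01,
) -> float:
    """RMSSD (ms) over beats inside the window.

    Successive differences are only formed between entries the device marked
    consecutive: the offset gap between neighbours equals the later interval
    within ``gap_tol_s``.  Returns NaN when fewer than ``min_beats``
    successive pairs qualify — with sparse valid IBI data this is the norm,
    which is why HRV is displayed but excluded from inference.
    """
    if len(ibi) < 2:
        return float("nan")
    t = ibi.beat_times()
    inside = (t >= window_start) & (t < window_end)
    consecutive = np.isclose(np.diff(ibi.offsets), ibi.intervals[1:], atol=gap_tol_s)
    usable = consecutive & inside[1:] & inside[:-1]
    diffs = np.diff(ibi.intervals)[usable]
    if len(diffs) < min_beats:
        return float("nan")
    return float(np.sqrt(np.mean(diffs**2)) * 1000.0)
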