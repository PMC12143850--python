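"""Derived measures: movement, SCL, SCR peaks, PPM, RMSSD."""

import numpy as np
import pytest

from e4arousal.e4io import IbiSeries, SignalChannel
from e4arousal.features import (
    ScrPeak,
    detect_scr_peaks,
    movement_magnitude,
    peaks_per_minute,
    rmssd,
    smooth_eda,
)
from e4arousal.quality import ARTIFACT, VALID, QualityMask
from e4arousal.synth import bateman_kernel
from conftest import T0


def acc_axes(x, y, z):
    return tuple(
        SignalChannel(n, T0, 32.0, np.asarray(v, float))
        for n, v in (("ACC_X", x), ("ACC_Y", y), ("ACC_Z", z))
    )


def eda_channel(values):
    return SignalChannel("EDA", T0, 4.0, np.asarray(values, float))


def sample_mask(labels_per_epoch, epoch_s=5.0):
    labels = np.array(labels_per_epoch, dtype=object)
    return QualityMask("EDA", T0, epoch_s, labels, [()] * len(labels), epoch_s * len(labels))


class TestMovement:
    def test_device_at_rest_measures_zero_any_orientation(self, rng):
        n = 32 * 300
        for _ in range(5):
            g = rng.normal(size=3)
            g /= np.linalg.norm(g)
            x, y, z = (np.full(n, gi) for gi in g)
            out = movement_magnitude(*acc_axes(x, y, z))
            assert np.nanmax(out.values) < 1e-9

    def test_sinusoid_recovers_rectified_mean(self):
        # 0.5 g oscillation on one axis: mean |0.5 sin| = 2*0.5/pi
        n = 32 * 600
        t = np.arange(n) / 32.0
        x = 0.5 * np.sin(2 * np.pi * 1.0 * t)
        out = movement_magnitude(*acc_axes(x, np.zeros(n), np.ones(n)))
        assert np.nanmean(out.values) == pytest.approx(2 * 0.5 / np.pi, rel=0.02)

    def test_all_zero_axes_measure_zero(self):
        n = 32 * 60
        out = movement_magnitude(*acc_axes(np.zeros(n), np.zeros(n), np.zeros(n)))
        assert np.nanmax(out.values) == 0.0

    def test_axis_length_mismatch_errors(self):
        x = SignalChannel("ACC_X", T0, 32.0, np.zeros(100))
        y = SignalChannel("ACC_Y", T0, 32.0, np.zeros(90))
        z = SignalChannel("ACC_Z", T0, 32.0, np.zeros(100))
        with pytest.raises(ValueError, match="length"):
            movement_magnitude(x, y, z)


def brute_force_masked_mean(values, valid, window):
    """Direct O(n*w) centered masked moving average."""
    n = len(values)
    half_lo = (window - 1) // 2
    half_hi = window - half_lo
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(i - half_lo, 0), min(i + half_hi, n)
        sel = valid[lo:hi]
        if sel.any():
            out[i] = values[lo:hi][sel].mean()
    return out


class TestSmoothEda:
    def test_constant_valid_signal_is_unchanged(self):
        out = smooth_eda(eda_channel(np.full(200, 2.0)), None, window_s=30.0)
        np.testing.assert_allclose(out.values, 2.0)

    def test_matches_brute_force_masked_mean_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 200))
            vals = rng.uniform(0.1, 10, n)
            n_epochs = int(np.ceil(n / 20))
            labels = rng.choice([VALID, ARTIFACT], n_epochs, p=[0.8, 0.2])
            mask = sample_mask(list(labels))
            w_s = float(rng.choice([2.0, 7.5, 30.0]))
            out = smooth_eda(eda_channel(vals), mask, window_s=w_s, mask_output=False)
            valid = np.repeat(labels == VALID, 20)[:n]
            expected = brute_force_masked_mean(vals, valid, int(w_s * 4))
            np.testing.assert_allclose(out.values, expected, atol=1e-10, equal_nan=True)

    def test_step_midpoint_is_halfway(self):
        vals = np.concatenate([np.full(40, 1.0), np.full(40, 3.0)])
        out = smooth_eda(eda_channel(vals), None, window_s=8.0)
        # centered 32-sample window at the step edge averages 16+16 samples
        assert out.values[40] == pytest.approx(2.0, abs=0.07)

    def test_single_artifact_sample_excluded_from_window(self):
        vals = np.full(40, 2.0)
        vals[20:25] = 50.0
        labels = [VALID, ARTIFACT]  # second epoch bad
        out = smooth_eda(eda_channel(vals), sample_mask(labels), window_s=30.0, mask_output=False)
        np.testing.assert_allclose(out.values, 2.0)

    def test_masked_output_missing_on_invalid_epochs(self):
        vals = np.full(40, 2.0)
        out = smooth_eda(eda_channel(vals), sample_mask([VALID, ARTIFACT]), window_s=5.0)
        assert np.isfinite(out.values[:20]).all()
        assert np.isnan(out.values[20:]).all()


def inject_scr(eda, onset_idx, amp):
    k = bateman_kernel(4.0) * amp
    hi = min(onset_idx + len(k), len(eda))
    eda[onset_idx:hi] += k[: hi - onset_idx]
    return eda


class TestScrDetection:
    def test_flat_signal_has_no_peaks(self):
        assert detect_scr_peaks(eda_channel(np.full(400, 2.0))) == []

    def test_single_injected_bump_yields_one_peak(self):
        eda = inject_scr(np.full(400, 2.0), 200, 0.3)
        peaks = detect_scr_peaks(eda_channel(eda), min_amplitude=0.05)
        assert len(peaks) == 1
        assert peaks[0].amplitude == pytest.approx(0.3, rel=0.2)
        assert peaks[0].peak_time > peaks[0].onset_time

    def test_subthreshold_bump_not_counted(self):
        eda = inject_scr(np.full(400, 2.0), 200, 0.03)
        assert detect_scr_peaks(eda_channel(eda), min_amplitude=0.05) == []

    def test_bump_inside_artifact_epoch_suppressed(self):
        eda = inject_scr(np.full(400, 2.0), 200, 0.3)
        labels = [VALID] * 20
        labels[10] = ARTIFACT  # epoch covering samples 200..220
        peaks = detect_scr_peaks(eda_channel(eda), sample_mask(labels))
        assert peaks == []

    def test_count_scales_linearly_with_injected_bumps(self, rng):
        for n_bumps in (2, 5, 9):
            eda = np.full(4 * 600, 2.0)
            onsets = np.linspace(100, len(eda) - 200, n_bumps).astype(int)
            for o in onsets:
                inject_scr(eda, o, 0.4)
            peaks = detect_scr_peaks(eda_channel(eda))
            assert len(peaks) == n_bumps


class TestPpm:
    def test_fifteen_peaks_in_five_valid_minutes(self):
        peaks = [ScrPeak(T0 + 10 * i, T0 + 10 * i + 2, 0.2) for i in range(15)]
        assert peaks_per_minute(peaks, T0, T0 + 300) == pytest.approx(3.0)

    def test_no_peaks_is_zero_not_missing(self):
        assert peaks_per_minute([], T0, T0 + 300) == 0.0

    def test_valid_minute_denominator(self):
        peaks = [ScrPeak(T0 + 20 * i, T0 + 20 * i + 2, 0.2) for i in range(6)]
        # 5-minute window, 2 minutes artifact -> 3 valid minutes
        assert peaks_per_minute(peaks, T0, T0 + 300, valid_fraction=3 / 5) == pytest.approx(2.0)

    def test_zero_valid_minutes_is_missing(self):
        assert np.isnan(peaks_per_minute([], T0, T0 + 300, valid_fraction=0.0))


class TestRmssd:
    def test_constant_series_is_exactly_zero(self):
        ibi = IbiSeries(T0, np.array([1.0, 1.8, 2.6]), np.array([0.8, 0.8, 0.8]))
        assert rmssd(ibi, T0, T0 + 10, min_beats=1) == 0.0

    def test_single_difference_of_100ms(self):
        ibi = IbiSeries(T0, np.array([1.0, 1.8]), np.array([0.7, 0.8]))
        # offsets gap 0.8 == interval 0.8 -> consecutive; diff 0.1 s
        assert rmssd(ibi, T0, T0 + 10, min_beats=1) == pytest.approx(100.0)

    def test_nonconsecutive_gap_contributes_nothing(self):
        ibi = IbiSeries(T0, np.array([1.0, 1.8, 9.0]), np.array([0.7, 0.8, 0.6]))
        only_pair = rmssd(ibi, T0, T0 + 20, min_beats=1)
        assert only_pair == pytest.approx(100.0)  # the 0.6 interval is isolated

    def test_too_few_pairs_is_missing(self):
        ibi = IbiSeries(T0, np.array([1.0, 1.8]), np.array([0.7, 0.8]))
        assert np.isnan(rmssd(ibi, T0, T0 + 10, min_beats=10))

    def test_translation_invariance(self, rng):
        offs = np.cumsum(rng.uniform(0.6, 1.0, 30))
        ivals = np.concatenate([[offs[0]], np.diff(offs)])
        a = rmssd(IbiSeries(T0, offs, ivals), T0, T0 + 40, min_beats=1)
        b = rmssd(IbiSeries(T0 + 500, offs, ivals), T0 + 500, T0 + 540, min_beats=1)
        assert a == pytest.approx(b)

    def test_matches_brute_force_on_random_windows(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            ivals = rng.uniform(0.5, 1.2, n)
            offs = np.cumsum(ivals)
            drop = rng.random(n) < 0.2  # perturb some offsets -> non-consecutive
            offs = offs + np.where(drop, rng.uniform(0.1, 0.3, n), 0.0)
            offs = np.sort(offs)
            ibi = IbiSeries(T0, offs, ivals)
            w0, w1 = T0, T0 + float(offs[-1]) + 1
            got = rmssd(ibi, w0, w1, min_beats=1)
            diffs = [
                ivals[k] - ivals[k - 1]
                for k in range(1, n)
                if abs((offs[k] - offs[k - 1]) - ivals[k]) <= 0.01
            ]
            if not diffs:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(np.sqrt(np.mean(np.square(diffs))) * 1000)
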