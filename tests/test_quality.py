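"""Artifact classification, off-wrist detection and retention accounting."""

import numpy as np
import pytest

from e4arousal.e4io import SignalChannel
from e4arousal.quality import (
    ARTIFACT,
    OFF_WRIST,
    VALID,
    QualityConfig,
    QualityMask,
    classify_eda_epochs,
    detect_off_wrist,
    invalidate_hr_off_wrist,
    retention_percent,
    retention_report,
)
from conftest import T0, build_session


def eda_channel(values, start=T0):
    return SignalChannel("EDA", start, 4.0, np.asarray(values, dtype=float))


def temp_channel(values, start=T0):
    return SignalChannel("TEMP", start, 4.0, np.asarray(values, dtype=float))


def brute_force_labels(eda, temp, cfg: QualityConfig):
    """Independent per-epoch rule evaluation by direct looping."""
    spe = int(cfg.epoch_s * 4)
    labels = []
    for i in range(0, len(eda), spe):
        seg = eda[i : i + spe]
        tseg = temp[i : i + spe]
        fired = (
            np.any(seg < cfg.eda_floor_uS)
            or np.any(seg > cfg.eda_ceiling_uS)
            or np.any(np.abs(np.diff(seg)) * 4 > cfg.max_slope_uS_per_s)
            or (i + spe < len(eda) and abs(eda[i + spe] - seg[-1]) * 4 > cfg.max_slope_uS_per_s)
            or np.mean(tseg) < cfg.temp_floor_C
        )
        labels.append(ARTIFACT if fired else VALID)
    return np.array(labels, dtype=object)


class TestClassifyEpochs:
    def test_matches_brute_force_rules_on_random_signals(self, rng):
        cfg = QualityConfig()
        for _ in range(100):
            n = int(rng.integers(40, 400))
            eda = rng.uniform(0.02, 3.0, n).cumsum() % 5  # wandering, occasional wraps
            temp = rng.uniform(28.0, 36.0, n)
            mask = classify_eda_epochs(eda_channel(eda), temp_channel(temp), config=cfg)
            np.testing.assert_array_equal(mask.labels, brute_force_labels(eda, temp, cfg))

    def test_step_jump_fires_slope_rule(self):
        eda = np.full(20, 0.5)
        eda[10:] = 5.5  # 5 uS in one 4 Hz sample = 20 uS/s
        mask = classify_eda_epochs(eda_channel(eda), temp_channel(np.full(20, 33.0)))
        assert mask.labels[0] == ARTIFACT
        assert "eda_slope" in mask.provenance[0]

    def test_clean_constant_signal_is_valid(self):
        mask = classify_eda_epochs(
            eda_channel(np.full(40, 2.0)), temp_channel(np.full(40, 33.0))
        )
        assert all(l == VALID for l in mask.labels)

    def test_all_zero_record_is_all_artifact_via_floor(self):
        mask = classify_eda_epochs(eda_channel(np.zeros(80)), temp_channel(np.full(80, 33.0)))
        assert all(l == ARTIFACT for l in mask.labels)
        assert all("eda_floor" in p for p in mask.provenance)

    def test_cold_skin_fires_temperature_rule(self):
        mask = classify_eda_epochs(
            eda_channel(np.full(20, 2.0)), temp_channel(np.full(20, 27.0))
        )
        assert mask.labels[0] == ARTIFACT
        assert "temp_floor" in mask.provenance[0]

    def test_missing_temperature_skips_rule_with_warning(self):
        with pytest.warns(UserWarning, match="temperature"):
            mask = classify_eda_epochs(eda_channel(np.full(20, 2.0)), None)
        assert all(l == VALID for l in mask.labels)

    def test_empty_channel_gives_empty_mask(self):
        mask = classify_eda_epochs(eda_channel([]), temp_channel([]))
        assert mask.n_epochs == 0


def run_mask(labels, epoch_s=5.0):
    labels = np.array(labels, dtype=object)
    return QualityMask("EDA", T0, epoch_s, labels, [()] * len(labels), epoch_s * len(labels))


class TestOffWrist:
    def test_twelve_minute_artifact_run_becomes_off_wrist(self):
        n_run = 144  # 12 min of 5 s epochs
        mask = run_mask([VALID] * 10 + [ARTIFACT] * n_run + [VALID] * 10)
        out = detect_off_wrist(mask, 600.0)
        assert all(l == OFF_WRIST for l in out.labels[10 : 10 + n_run])
        assert all(l == VALID for l in out.labels[:10])

    def test_nine_minute_run_stays_artifact(self):
        mask = run_mask([ARTIFACT] * 108)  # 9 min
        out = detect_off_wrist(mask, 600.0)
        assert all(l == ARTIFACT for l in out.labels)

    def test_alternating_epochs_never_off_wrist(self):
        mask = run_mask([VALID, ARTIFACT] * 200)
        out = detect_off_wrist(mask, 600.0)
        assert OFF_WRIST not in set(out.labels)

    def test_idempotent_and_never_touches_valid(self, rng):
        labels = rng.choice([VALID, ARTIFACT], 500, p=[0.3, 0.7])
        mask = run_mask(list(labels))
        once = detect_off_wrist(mask, 600.0)
        twice = detect_off_wrist(once, 600.0)
        np.testing.assert_array_equal(once.labels, twice.labels)
        valid_before = mask.labels == VALID
        assert all(once.labels[valid_before] == VALID)

    def test_boundary_run_exactly_at_threshold_relabels(self):
        mask = run_mask([ARTIFACT] * 120)  # exactly 600 s
        out = detect_off_wrist(mask, 600.0)
        assert all(l == OFF_WRIST for l in out.labels)


class TestHrInvalidation:
    def test_off_wrist_hr_becomes_missing(self):
        labels = [OFF_WRIST] * 120 + [VALID] * 120
        mask = run_mask(labels)
        hr = SignalChannel("HR", T0, 1.0, np.full(1200, 140.0))
        out = invalidate_hr_off_wrist(hr, mask)
        assert np.isnan(out.values[:600]).all()
        assert (out.values[600:1200] == 140.0).all()

    def test_no_off_wrist_is_identity(self):
        mask = run_mask([VALID] * 120)
        hr = SignalChannel("HR", T0, 1.0, np.full(600, 95.0))
        out = invalidate_hr_off_wrist(hr, mask)
        np.testing.assert_array_equal(out.values, hr.values)

    def test_whole_session_off_wrist_blanks_everything(self):
        mask = run_mask([OFF_WRIST] * 120)
        hr = SignalChannel("HR", T0, 1.0, np.full(600, 150.0))
        assert np.isnan(invalidate_hr_off_wrist(hr, mask).values).all()


def mask_with_hours(raw_h: float, off_h: float, artifact_h: float) -> QualityMask:
    """A mask whose stage hours are exactly as requested (5 s epochs)."""
    n_raw = round(raw_h * 720)
    n_off = round(off_h * 720)
    n_art = round(artifact_h * 720)
    labels = [OFF_WRIST] * n_off + [ARTIFACT] * n_art + [VALID] * (n_raw - n_off - n_art)
    return run_mask(labels)


class TestRetention:
    def test_study_scale_percentages(self, quiet_session):
        # raw 39.3 h; 34.8 h after long-noise removal (-11%); 26.1 h after
        # artifact removal (-25%)
        mask = mask_with_hours(39.3, 39.3 - 34.8, 34.8 - 26.1)
        report = retention_report([mask], [quiet_session])
        row = report.loc["P01"]
        assert row["raw_h"] == pytest.approx(39.3)
        assert row["after_long_noise_h"] == pytest.approx(34.8)
        assert row["after_artifact_h"] == pytest.approx(26.1)
        assert row["long_noise_pct"] == -11
        assert row["artifact_pct"] == -25

    def test_all_valid_session_reduces_zero(self, quiet_session):
        mask = mask_with_hours(10.0, 0.0, 0.0)
        row = retention_report([mask], [quiet_session]).loc["P01"]
        assert row["long_noise_pct"] == 0 and row["artifact_pct"] == 0

    def test_stage_hours_are_monotone(self, rng, quiet_session):
        for _ in range(20):
            labels = rng.choice([VALID, ARTIFACT, OFF_WRIST], 500)
            row = retention_report([run_mask(list(labels))], [quiet_session]).loc["P01"]
            assert row["raw_h"] >= row["after_long_noise_h"] >= row["after_artifact_h"]


def test_retention_percent_is_signed_integer():
    assert retention_percent(39.3, 34.8) == -11
    assert retention_percent(34.8, 26.1) == -25
    assert retention_percent(10.0, 10.0) == 0
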