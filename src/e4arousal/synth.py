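"""Synthetic cohort generator: E4-style sessions plus traffic-light logs.

Emulates the study inputs end to end so every pipeline stage can be exercised
and effects can be recovered against known ground truth:

* EDA (4 Hz)  — tonic level with slow drift (OU process + slow sinusoid) plus
  phasic SCRs (Bateman-kernel bumps at Poisson times) and sensor noise;
* TEMP (4 Hz) — ~33 °C on-wrist, exponential decay toward ambient off-wrist;
* ACC (32 Hz) — gravity plus noise and movement bursts;
* HR (1 Hz)   — AR(1) around an age-appropriate baseline (APLS norm bands:
  80–120 bpm ages 6–12, 60–100 bpm ages 12–14), *artificially elevated* during
  off-wrist spans — the device keeps reporting plausible-but-wrong HR when
  unworn, so off-wrist invalidation is genuinely exercised;
* IBI         — sparse segments of valid beats (valid IBI covers only a small
  fraction of wear time);
* behavior    — red/orange/green observation rows at incident onsets, written
  at minute resolution.

During each red incident window an additive boxcar raises HR and SCL, extra
SCRs are injected and a movement oscillation is added; the injected shifts
are the ground truth the frame analysis should recover.  Orange events carry
no physiological effect by default (observed disruptive behavior with and
without an arousal response both occur in practice).

Wearing windows follow the study settings: clinic 08:00–20:00, daycare
08:00–15:00, five consecutive days.  Seeded runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as Date, datetime, time as dtime, timedelta
from pathlib import Path
from zoneinfo import ZoneInfo

import numpy as np
from scipy.signal import fftconvolve, lfilter

from .e4io import E4Session, IbiSeries, SignalChannel, write_session
from .observations import ObservationEvent, ObservationLog, write_observations

__all__ = [
    "SyntheticConfig",
    "Participant",
    "CohortData",
    "generate_cohort",
    "iter_cohort_days",
    "generate_day",
    "generate_worked_day",
    "write_cohort",
]

RED_PHRASES = ("hitting", "kicking", "throwing objects", "fighting", "severe tantrum")
ORANGE_PHRASES = ("shouting", "refusing instructions", "provoking", "running off")
GREEN_PHRASES = ("compliment for correct behavior", "calm cooperation")


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings; defaults reproduce the study design."""

    n_participants: int = 30
    clinic_fraction: float = 0.6
    days: int = 5
    start_date: str = "2023-03-06"  # a Monday
    timezone: str = "Europe/Amsterdam"
    clinic_hours: tuple[float, float] = (8.0, 20.0)
    daycare_hours: tuple[float, float] = (8.0, 15.0)
    age_range: tuple[int, int] = (6, 14)

    # heart rate
    hr_sd_bpm: float = 6.0
    hr_tau_s: float = 200.0

    # electrodermal activity
    scl_base_range_uS: tuple[float, float] = (1.0, 8.0)
    scl_drift_sd_uS: float = 0.5
    scl_drift_tau_s: float = 1800.0
    scl_slow_amp_uS: float = 0.3  # slow within-day sinusoid
    eda_noise_sd_uS: float = 0.01
    scr_rate_per_min: float = 2.6
    scr_amp_mean_uS: float = 0.3
    scr_amp_sigma: float = 0.4  # lognormal shape
    scr_rise_s: float = 0.75
    scr_decay_s: float = 3.0
    #: minimum inter-response interval: SCRs closer than this superpose into a
    #: single countable peak, so the generator emits resolvable responses only
    scr_refractory_s: float = 4.0

    # behavior
    red_per_day: float = 2.0
    orange_per_day: float = 2.0
    green_per_day: float = 1.0
    min_red_separation_s: float = 600.0
    orange_effect_scale: float = 0.0

    # injected incident effects (additive boxcar over the 5-minute window)
    effect_hr_bpm: float = 9.0
    effect_scl_uS: float = 0.15
    effect_ppm: float = 0.6
    effect_movement_g: float = 0.02
    incident_window_s: float = 300.0

    # nuisance processes
    artifact_bursts_per_hour: float = 2.0
    artifact_duration_s: tuple[float, float] = (5.0, 40.0)
    artifact_noise_sd_uS: float = 2.0
    off_wrist_per_day: float = 0.3
    off_wrist_duration_s: tuple[float, float] = (720.0, 2400.0)
    off_wrist_hr_bpm: tuple[float, float] = (140.0, 170.0)
    temp_on_wrist_C: float = 33.0
    temp_ambient_C: float = 26.0
    movement_bursts_per_hour: float = 20.0
    burst_duration_s: tuple[float, float] = (5.0, 60.0)
    burst_amp_g: tuple[float, float] = (0.1, 0.8)

    # IBI
    ibi_segments_per_day: float = 3.0
    ibi_segment_s: tuple[float, float] = (30.0, 120.0)
    ibi_jitter_s: float = 0.03

    include_bvp: bool = True

    def wearing_hours(self, setting: str) -> tuple[float, float]:
        return self.clinic_hours if setting == "clinic" else self.daycare_hours


@dataclass
class Participant:
    participant_id: str
    age: int
    setting: str
    hr_baseline_bpm: float
    scl_base_uS: float


def hr_norm_band(age: int) -> tuple[float, float]:
    """APLS pediatric HR norm band for the age."""
    return (80.0, 120.0) if age < 12 else (60.0, 100.0)


def draw_participants(cfg: SyntheticConfig, rng: np.random.Generator) -> list[Participant]:
    n_clinic = int(round(cfg.n_participants * cfg.clinic_fraction))
    out = []
    for i in range(cfg.n_participants):
        age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        lo, hi = hr_norm_band(age)
        out.append(
            Participant(
                participant_id=f"P{i + 1:02d}",
                age=age,
                setting="clinic" if i < n_clinic else "daycare",
                # baseline drawn inside the norm band, away from its edges so
                # ordinary fluctuation stays in range
                hr_baseline_bpm=float(rng.uniform(lo + 8, hi - 12)),
                scl_base_uS=float(rng.uniform(*cfg.scl_base_range_uS)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# signal-building blocks


def _ou(n: int, sd: float, tau_s: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path (burn-in discarded)."""
    if n == 0:
        return np.empty(0)
    a = np.exp(-1.0 / (tau_s * rate))
    s = sd * np.sqrt(1.0 - a * a)
    burn = int(5 * tau_s * rate)
    e = rng.standard_normal(n + burn)
    x = lfilter([s], [1.0, -a], e)
    return x[burn:]


def _smooth_ou(
    n: int, sd: float, tau_s: float, rate: float, rng: np.random.Generator, gen_dt_s: float = 10.0
) -> np.ndarray:
    """OU drift generated on a coarse grid and interpolated to the sample rate.

    Tonic processes (SCL level, skin temperature) vary on the minutes scale;
    generating them directly at the channel rate would add sample-to-sample
    jitter with no physiological counterpart (and would masquerade as phasic
    activity).  The interpolated path is band-limited with a short Gaussian
    filter so knot kinks do not register as phasic bumps either.
    """
    if n == 0:
        return np.empty(0)
    gen_rate = 1.0 / gen_dt_s
    m = int(np.ceil(n / rate * gen_rate)) + 2
    coarse = _ou(m, sd, tau_s, gen_rate, rng)
    path = np.interp(np.arange(n) / rate, np.arange(m) * gen_dt_s, coarse)
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(path, sigma=4.0 * rate, mode="nearest")


def bateman_kernel(rate: float, rise_s: float = 0.75, decay_s: float = 3.0) -> np.ndarray:
    """Unit-peak SCR impulse response exp(-t/τd) − exp(-t/τr)."""
    t = np.arange(0, decay_s * 8, 1.0 / rate)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def _scr_train(
    n: int, rate: float, event_idx: np.ndarray, amps: np.ndarray, kernel: np.ndarray
) -> np.ndarray:
    impulses = np.zeros(n)
    ok = (event_idx >= 0) & (event_idx < n)
    np.add.at(impulses, event_idx[ok], amps[ok])
    return fftconvolve(impulses, kernel)[:n]


def _boxcar(n: int, rate: float, t0: float, spans, height: float, ramp_s: float = 0.0) -> np.ndarray:
    """Additive boxcar; ``ramp_s`` makes the edges linear ramps.

    Tonic (SCL) incident responses use ramped edges — a step edge would be a
    phasic artifact the peak detector picks up, which no gradual tonic rise
    produces.
    """
    out = np.zeros(n)
    r = int(round(ramp_s * rate))
    for s, e in spans:
        i0 = max(int(np.ceil((s - t0) * rate)), 0)
        i1 = min(int(np.ceil((e - t0) * rate)), n)
        if i1 <= i0:
            continue
        shape = np.full(i1 - i0, height)
        if r > 0:
            up = np.linspace(0, height, min(r, len(shape)), endpoint=False)
            shape[: len(up)] = up
        out[i0:i1] += shape
        if r > 0:  # decay past the window end
            j1 = min(i1 + r, n)
            out[i1:j1] += np.linspace(height, 0, r, endpoint=False)[: j1 - i1]
    return out


def _minute_times(
    rng: np.random.Generator, t0: float, t1: float, count: int, min_sep_s: float, margin_s: float
) -> np.ndarray:
    """Event onsets on whole minutes, at least ``min_sep_s`` apart."""
    lo = int(np.ceil((t0 + margin_s) / 60.0))
    hi = int(np.floor((t1 - margin_s) / 60.0))
    if hi <= lo or count <= 0:
        return np.empty(0)
    minutes = rng.permutation(np.arange(lo, hi)) * 60.0
    chosen: list[float] = []
    for m in minutes:
        if len(chosen) >= count:
            break
        if all(abs(m - c) >= min_sep_s for c in chosen):
            chosen.append(float(m))
    return np.sort(np.array(chosen))


def _spans(rng, t0, t1, count, dur_range) -> list[tuple[float, float]]:
    out = []
    for _ in range(count):
        d = float(rng.uniform(*dur_range))
        if t1 - t0 <= d:
            continue
        s = float(rng.uniform(t0, t1 - d))
        out.append((s, s + d))
    return sorted(out)


def _merge_spans(spans):
    merged: list[list[float]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------


def generate_day(
    participant: Participant,
    day_index: int,
    date: Date,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[E4Session, list[ObservationEvent], dict]:
    """One participant-day: session, observation events and ground truth."""
    tz = ZoneInfo(cfg.timezone)
    h0, h1 = cfg.wearing_hours(participant.setting)
    t0 = datetime.combine(date, dtime(int(h0), int(round((h0 % 1) * 60))), tz).timestamp()
    dur = (h1 - h0) * 3600.0
    t1 = t0 + dur
    n4, n1, n32 = int(dur * 4), int(dur), int(dur * 32)

    # --- behavior -----------------------------------------------------------
    w = cfg.incident_window_s
    n_red = int(rng.poisson(cfg.red_per_day))
    red_times = _minute_times(rng, t0, t1, n_red, cfg.min_red_separation_s, margin_s=w + 60)
    n_orange = int(rng.poisson(cfg.orange_per_day))
    orange_times = _minute_times(rng, t0, t1, n_orange, 120.0, margin_s=60)
    n_green = int(rng.poisson(cfg.green_per_day))
    green_times = _minute_times(rng, t0, t1, n_green, 120.0, margin_s=60)

    red_spans = [(t, t + w) for t in red_times]
    orange_spans = [(t, t + w) for t in orange_times]

    # --- nuisance spans -----------------------------------------------------
    off_spans = _merge_spans(
        _spans(rng, t0, t1, int(rng.poisson(cfg.off_wrist_per_day)), cfg.off_wrist_duration_s)
    )
    art_spans = _spans(
        rng, t0, t1, int(rng.poisson(cfg.artifact_bursts_per_hour * dur / 3600)), cfg.artifact_duration_s
    )

    # --- EDA ----------------------------------------------------------------
    tonic = (
        participant.scl_base_uS
        + _smooth_ou(n4, cfg.scl_drift_sd_uS, cfg.scl_drift_tau_s, 4.0, rng)
        + cfg.scl_slow_amp_uS
        * np.sin(2 * np.pi * np.arange(n4) / (4.0 * 4 * 3600.0) + rng.uniform(0, 2 * np.pi))
    )
    base_rate_s = cfg.scr_rate_per_min / 60.0
    n_scr = int(rng.poisson(base_rate_s * dur))
    base_t = np.sort(rng.uniform(0, dur, n_scr))
    # enforce the inter-response refractory interval: keep the first of any
    # unresolvable cluster
    kept: list[float] = []
    for t in base_t:
        if not kept or t - kept[-1] >= cfg.scr_refractory_s:
            kept.append(float(t))
    scr_t = np.array(kept)
    # extra incident responses are placed where they stay resolvable, so the
    # injected count is identifiable by any trough-to-peak counter
    extra_rate_s = cfg.effect_ppm / 60.0
    extras: list[float] = []
    for spans, scale in ((red_spans, 1.0), (orange_spans, cfg.orange_effect_scale)):
        for s, e in spans:
            k = int(rng.poisson(extra_rate_s * scale * (e - s)))
            placed = 0
            for _ in range(20 * k):
                if placed >= k:
                    break
                cand = float(rng.uniform(s - t0, e - t0))
                pool = np.concatenate([scr_t, np.array(extras)])
                if not len(pool) or np.min(np.abs(pool - cand)) >= cfg.scr_refractory_s:
                    extras.append(cand)
                    placed += 1
    scr_t = np.sort(np.concatenate([scr_t, np.array(extras)]))
    mu = np.log(cfg.scr_amp_mean_uS) - cfg.scr_amp_sigma**2 / 2
    amps = rng.lognormal(mu, cfg.scr_amp_sigma, len(scr_t))
    kernel = bateman_kernel(4.0, cfg.scr_rise_s, cfg.scr_decay_s)
    phasic = _scr_train(n4, 4.0, np.round(scr_t * 4).astype(int), amps, kernel)
    eda = (
        tonic
        + phasic
        + _boxcar(n4, 4.0, t0, red_spans, cfg.effect_scl_uS, ramp_s=60.0)
        + _boxcar(n4, 4.0, t0, orange_spans, cfg.effect_scl_uS * cfg.orange_effect_scale, ramp_s=60.0)
        + rng.normal(0, cfg.eda_noise_sd_uS, n4)
    )
    eda = np.clip(eda, 0.06, None)  # healthy on-wrist signal stays above the contact floor
    for s, e in art_spans:
        i0, i1 = int((s - t0) * 4), int((e - t0) * 4)
        eda[i0:i1] += rng.normal(0, cfg.artifact_noise_sd_uS, max(i1 - i0, 0))

    # --- TEMP ---------------------------------------------------------------
    temp = (
        cfg.temp_on_wrist_C
        + _smooth_ou(n4, 0.2, 600.0, 4.0, rng)
        + rng.normal(0, 0.05, n4)
    )

    # --- HR -----------------------------------------------------------------
    hr = (
        participant.hr_baseline_bpm
        + _ou(n1, cfg.hr_sd_bpm, cfg.hr_tau_s, 1.0, rng)
        + _boxcar(n1, 1.0, t0, red_spans, cfg.effect_hr_bpm)
        + _boxcar(n1, 1.0, t0, orange_spans, cfg.effect_hr_bpm * cfg.orange_effect_scale)
    )

    # --- ACC ----------------------------------------------------------------
    acc = rng.normal(0, 0.02, (3, n32))
    acc[2] += 1.0  # gravity
    tgrid32 = np.arange(n32) / 32.0
    n_bursts = int(rng.poisson(cfg.movement_bursts_per_hour * dur / 3600))
    for s, e in _spans(rng, t0, t1, n_bursts, cfg.burst_duration_s):
        i0, i1 = int((s - t0) * 32), int((e - t0) * 32)
        amp = rng.uniform(*cfg.burst_amp_g)
        f = rng.uniform(1.0, 4.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        osc = amp * np.sin(2 * np.pi * f * tgrid32[i0:i1] + rng.uniform(0, 2 * np.pi))
        acc[:, i0:i1] += direction[:, None] * osc
    for spans, scale in ((red_spans, 1.0), (orange_spans, cfg.orange_effect_scale)):
        # mean |A sin| = 2A/π, so A = Δg·π/2 injects a Δg mean-movement shift
        amp = cfg.effect_movement_g * np.pi / 2 * scale
        if amp <= 0:
            continue
        for s, e in spans:
            i0, i1 = int((s - t0) * 32), int((e - t0) * 32)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            osc = amp * np.sin(2 * np.pi * 2.0 * tgrid32[i0:i1] + rng.uniform(0, 2 * np.pi))
            acc[:, i0:i1] += direction[:, None] * osc

    # --- off-wrist overrides ------------------------------------------------
    for s, e in off_spans:
        i0, i1 = int((s - t0) * 4), int((e - t0) * 4)
        m = max(i1 - i0, 0)
        eda[i0:i1] = rng.uniform(0.0, 0.03, m)  # below the skin-contact floor
        decay = np.exp(-np.arange(m) / (120.0 * 4))
        temp[i0:i1] = cfg.temp_ambient_C + (cfg.temp_on_wrist_C - cfg.temp_ambient_C) * decay
        j0, j1 = int((s - t0) * 1), int((e - t0) * 1)
        level = rng.uniform(*cfg.off_wrist_hr_bpm)
        hr[j0:j1] = level + rng.normal(0, 3.0, max(j1 - j0, 0))
    hr = np.clip(hr, 40.0, 220.0)

    # --- BVP ----------------------------------------------------------------
    if cfg.include_bvp:
        n64 = int(dur * 64)
        tgrid64 = np.arange(n64) / 64.0
        bvp = 50.0 * np.sin(2 * np.pi * 1.2 * tgrid64) + rng.normal(0, 5.0, n64)
    else:
        bvp = np.zeros(0)

    # --- IBI ----------------------------------------------------------------
    offsets, intervals = [], []
    for s, e in _merge_spans(
        _spans(rng, t0, t1, int(rng.poisson(cfg.ibi_segments_per_day)), cfg.ibi_segment_s)
    ):
        cursor = s - t0
        base = 60.0 / participant.hr_baseline_bpm
        while cursor < e - t0:
            ibi = max(base + rng.normal(0, cfg.ibi_jitter_s), 0.25)
            cursor += ibi
            offsets.append(cursor)
            intervals.append(ibi)
    ibi = IbiSeries(t0, np.asarray(offsets), np.asarray(intervals))

    channels = {
        "EDA": SignalChannel("EDA", t0, 4.0, eda),
        "TEMP": SignalChannel("TEMP", t0, 4.0, temp),
        "ACC_X": SignalChannel("ACC_X", t0, 32.0, acc[0]),
        "ACC_Y": SignalChannel("ACC_Y", t0, 32.0, acc[1]),
        "ACC_Z": SignalChannel("ACC_Z", t0, 32.0, acc[2]),
        "BVP": SignalChannel("BVP", t0, 64.0, bvp),
        "HR": SignalChannel("HR", t0, 1.0, hr),
    }
    session = E4Session(
        participant.participant_id, participant.setting, day_index, channels, ibi, cfg.timezone
    )

    events = []
    for times, color, phrases in (
        (red_times, "red", RED_PHRASES),
        (orange_times, "orange", ORANGE_PHRASES),
        (green_times, "green", GREEN_PHRASES),
    ):
        for t in times:
            events.append(
                ObservationEvent(
                    participant.participant_id,
                    float(t),
                    color,
                    description=str(rng.choice(list(phrases))),
                    observer=str(rng.choice(["staff", "researcher", "teacher"])),
                )
            )

    truth = {
        "participant_id": participant.participant_id,
        "day_index": day_index,
        "red_times": [float(t) for t in red_times],
        "orange_times": [float(t) for t in orange_times],
        "off_wrist_spans": [[float(s), float(e)] for s, e in off_spans],
        "artifact_spans": [[float(s), float(e)] for s, e in art_spans],
        "effects": {
            "hr_bpm": cfg.effect_hr_bpm,
            "scl_uS": cfg.effect_scl_uS,
            "ppm": cfg.effect_ppm,
            "movement_g": cfg.effect_movement_g,
        },
        "hr_baseline_bpm": participant.hr_baseline_bpm,
        "wearing_window": [t0, t1],
    }
    return session, events, truth


def iter_cohort_days(cfg: SyntheticConfig, seed: int):
    """Yield (participant, session, events, truth) day by day.

    Streaming access for large cohorts: nothing forces all sessions to live
    in memory at once.  The draw order is fixed, so a given seed always
    produces the identical cohort.
    """
    rng = np.random.default_rng(seed)
    participants = draw_participants(cfg, rng)
    d0 = Date.fromisoformat(cfg.start_date)
    for p in participants:
        for day_index in range(1, cfg.days + 1):
            session, events, truth = generate_day(
                p, day_index, d0 + timedelta(days=day_index - 1), cfg, rng
            )
            yield p, session, events, truth


@dataclass
class CohortData:
    participants: list[Participant]
    sessions: list[E4Session]
    log: ObservationLog
    truths: list[dict] = field(default_factory=list)


def generate_cohort(cfg: SyntheticConfig, seed: int) -> CohortData:
    """Materialize a full cohort in memory (use the iterator for big runs)."""
    participants: dict[str, Participant] = {}
    sessions, events, truths = [], [], []
    for p, session, evs, truth in iter_cohort_days(cfg, seed):
        participants[p.participant_id] = p
        sessions.append(session)
        events.extend(evs)
        truths.append(truth)
    return CohortData(list(participants.values()), sessions, ObservationLog(events), truths)


def write_cohort(cfg: SyntheticConfig, seed: int, out_dir: str | Path) -> Path:
    """Write a cohort to disk in the exact dialects the readers consume.

    Layout: ``<out>/P01_day1/…`` raw session directories, ``observations.csv``
    and a ``ground_truth.json`` ledger (true incident times, injected effects,
    off-wrist spans).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events, truths = [], []
    for p, session, evs, truth in iter_cohort_days(cfg, seed):
        write_session(session, out / f"{p.participant_id}_day{session.day_index}")
        events.extend(evs)
        truths.append(truth)
    write_observations(ObservationLog(events), out / "observations.csv", cfg.timezone)
    (out / "ground_truth.json").write_text(json.dumps(truths, indent=1))
    return out


# ---------------------------------------------------------------------------
# scripted vignette days


def _inject_scl_bump(eda: np.ndarray, rate: float, idx: int, amp: float, cfg: SyntheticConfig):
    kernel = bateman_kernel(rate, rise_s=5.0, decay_s=60.0) * amp
    hi = min(idx + len(kernel), len(eda))
    eda[idx:hi] += kernel[: hi - idx]


def generate_worked_day(
    template: str, seed: int = 0
) -> tuple[E4Session, list[ObservationEvent], dict]:
    """A scripted single day reproducing a clinical vignette structure.

    ``frank_day1``: five orange incidents — two morning ones with no SCL
    response, a noon one with movement+HR and a slight SCL rise, two with a
    clear SCL peak — plus a substantial unexplained multi-measure peak around
    18:30 with no reported event.

    ``peter_day3``: SCL peaks during a late-morning treatment session, a minor
    SCL peak at a 15:00 orange incident, and an exercise bout where movement
    and SCL rise *together* (sweating, not stress — context matters when
    reading SCL).
    """
    if template not in ("frank_day1", "peter_day3"):
        raise ValueError(f"unknown template {template!r}")
    cfg = SyntheticConfig(
        red_per_day=0.0,
        orange_per_day=0.0,
        green_per_day=0.0,
        off_wrist_per_day=0.0,
        artifact_bursts_per_hour=0.5,
    )
    rng = np.random.default_rng(seed)
    p = Participant("frankX" if template == "frank_day1" else "peterY", 10 if template == "frank_day1" else 12,
                    "clinic", 95.0 if template == "frank_day1" else 82.0, 3.0)
    day_index = 1 if template == "frank_day1" else 3
    date = Date.fromisoformat(cfg.start_date) + timedelta(days=day_index - 1)
    session, _, truth = generate_day(p, day_index, date, cfg, rng)

    eda = session["EDA"].values
    hr = session["HR"].values
    accx = session["ACC_X"].values
    t0 = session["EDA"].start_time
    tz = ZoneInfo(cfg.timezone)

    def at(hhmm: str) -> float:
        h, m = map(int, hhmm.split(":"))
        return datetime.combine(date, dtime(h, m), tz).timestamp()

    events: list[ObservationEvent] = []

    def orange(hhmm: str, desc: str):
        events.append(ObservationEvent(p.participant_id, at(hhmm), "orange", desc, "staff"))

    if template == "frank_day1":
        # two school incidents without any SCL/HR response
        orange("09:10", "removed from class")
        orange("09:40", "removed from class")
        # noon: movement + HR + slight SCL while walking clinic -> school
        orange("12:00", "agitated while walking to school")
        _inject_scl_bump(eda, 4.0, int((at("12:00") - t0) * 4), 0.4, cfg)
        hr[int(at("12:00") - t0) : int(at("12:00") - t0) + 300] += 12.0
        i0 = int((at("12:00") - t0) * 32)
        accx[i0 : i0 + 300 * 32] += 0.3 * np.sin(np.arange(300 * 32) * 2 * np.pi * 2 / 32)
        # two afternoon incidents with a clear SCL peak
        for hhmm in ("14:30", "16:15"):
            orange(hhmm, "shouting at staff")
            _inject_scl_bump(eda, 4.0, int((at(hhmm) - t0) * 4), 1.2, cfg)
        # unexplained evening peak across measures, no event reported
        _inject_scl_bump(eda, 4.0, int((at("18:30") - t0) * 4), 1.5, cfg)
        hr[int(at("18:30") - t0) : int(at("18:30") - t0) + 240] += 15.0
        scripted = {
            "no_response_events": ["09:10", "09:40"],
            "unexplained_peak": "18:30",
            "unexplained_peak_utc": at("18:30"),
        }
    else:
        # treatment session with repeated SCL peaks, reported tension
        for hhmm in ("10:35", "10:50", "11:05"):
            _inject_scl_bump(eda, 4.0, int((at(hhmm) - t0) * 4), 1.0, cfg)
        # exercise: movement and SCL rise together (no incident)
        ex0, ex1 = at("13:00"), at("13:30")
        i0, i1 = int((ex0 - t0) * 4), int((ex1 - t0) * 4)
        eda[i0:i1] += np.linspace(0, 1.5, i1 - i0)
        j0, j1 = int((ex0 - t0) * 32), int((ex1 - t0) * 32)
        accx[j0:j1] += 0.5 * np.sin(np.arange(j1 - j0) * 2 * np.pi * 2.5 / 32)
        hr[int(ex0 - t0) : int(ex1 - t0)] += 20.0
        # 15:00 orange incident with a minor SCL peak
        orange("15:00", "upset about change in daily routine")
        _inject_scl_bump(eda, 4.0, int((at("15:00") - t0) * 4), 0.5, cfg)
        scripted = {
            "treatment_session": ["10:30", "11:15"],
            "exercise": ["13:00", "13:30"],
            "exercise_utc": [ex0, ex1],
        }

    truth["scripted"] = scripted
    return session, events, truth
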