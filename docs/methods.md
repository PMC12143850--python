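# Methods

`e4arousal` implements a wearable-psychophysiology analysis for children with
disruptive behavior in clinical care: raw wrist-worn multi-channel recordings
plus traffic-light behavioral observations go in; quality-masked signals,
derived arousal measures, incident-aligned 5-minute frames with within-person
matched references, and Bonferroni-corrected paired comparisons come out.
This note records the models, the defaults and why, and what the synthetic
validation does and does not show.

## Signals and units

Sessions follow the Empatica E4 raw-export convention: per-channel CSV with a
Unix start timestamp and a sampling rate header. EDA at 4 Hz (µS), skin
temperature at 4 Hz (°C), triaxial acceleration at 32 Hz (raw counts, 1/64 g
per count), BVP at 64 Hz (arbitrary units, kept only as provenance for the
device-derived HR), HR at 1 Hz (bpm), and an irregular inter-beat-interval
file. Timestamps are held in UTC; anything clock-of-day (reference matching,
dashboard axes) goes through the session's IANA timezone, because
observations are recorded in local clinic time. Missing data is an explicit
NaN, never 0 — a zero EDA reading is informative (no skin contact).

IBI entries outside (0.2, 3.0) s are discarded at parse as physiologically
impossible beats; a non-monotone offset column rejects the whole series with
a warning but never the session.

## Quality masking

EDA validity is classified on 5 s epochs by transparent rules, each
individually configurable (`quality.*`):

| rule | default | rationale |
|---|---|---|
| EDA floor | 0.05 µS | near-zero conductance = no skin contact |
| EDA ceiling | 60 µS | out of physiological range |
| max slope | 10 µS/s | faster-than-physiological change |
| temperature floor | 30 °C | skin contact lost |
| long-noise threshold | 600 s | off-wrist if no valid data for 10 min |

An epoch is artifact as soon as any rule fires anywhere inside it; this makes
off-wrist detection conservative (edge epochs that are only partially
off-wrist still join the run). Maximal runs of invalid epochs of at least the
long-noise threshold are relabeled *off-wrist*; the distinction matters
because retention is accounted in two stages (long noise first, in-signal
artifacts second) and because the device reports a plausible-looking but
artificially high HR even when unworn — off-wrist spans are therefore
propagated to HR as missing. The classifier is rule-based by design; no
learned artifact model is involved.

## Derived measures

**Movement (g).** The static gravity component is estimated per axis by a
moving median and subtracted; the Euclidean norm of the residual is the
instantaneous movement, bin-averaged to 1 Hz. Per-axis estimation (rather
than a median of the norm) makes a resting device read exactly 0 g in any
orientation and recovers the rectified mean 2A/π of a pure A-sinusoid. The
median is computed over non-overlapping 60 s blocks and interpolated — exact
in both regimes above at a fraction of a rolling median's cost.

**SCL (µS).** The tonic level is a centered 30 s moving average of raw EDA
over valid samples only (a window with no valid samples is missing, and the
analysis output is additionally masked wherever the source epoch is
invalid). A moving average on the raw signal tracks a properly filtered
signal closely at this window length, and is what the clinical dashboard
displayed.

**SCR peaks and PPM.** Phasic = raw − SCL. The phasic signal is low-pass
filtered with a 0.5 s moving average (an SCR is an order of magnitude slower
than the sensor noise, so the response survives while noise extrema can no
longer reach the amplitude criterion), then local maxima with prominence ≥
0.05 µS are counted when the rise from the preceding trough — the minimum
within the admissible rise window — is at least 0.05 µS over 0.25–5 s, with
≥ 1 s between peaks. The 5 s upper rise bound rejects slow rebounds of the
moving-average baseline, which are not skin-conductance responses. Peaks in
invalid epochs are discarded. PPM divides the peak count by *valid* minutes
by default (`ppm.denominator: valid|wall`), so artifact time does not
deflate the rate — consistent with excluding artifact-heavy frames outright.

**RMSSD (ms).** Computed only from successive differences between beats the
device marked consecutive (offset gap equals the interval within 10 ms), and
reported missing below 10 such pairs. On this device valid IBI covers only a
small fraction of wear time, so HRV is displayed on the dashboard but
excluded from inference.

## Frames and pairing

A red (physical aggression) observation anchors a 5-minute frame at its
recorded time; red events within one frame length merge into one frame at
the earliest onset so a single escalation is not double-counted. References
are same-participant windows at the same local clock time (to the second) on
every other wearing day of the same 5-day block. Exclusions, in order and
each with one recorded reason: insufficient recording of the window (< 80%
by default), aggression overlap, and more than 75% EDA artifacts — *strictly*
more, so a frame at exactly 75% is retained. The artifact filter uses the EDA
mask alone, for incident and reference frames alike, matching the single
stated filter of the protocol. Exclusion accounting conserves counts.

The aggression-overlap test treats a logged event as an *episode*: onset to
onset + 300 s (configurable), widened by the ±60 s timestamp uncertainty of
hand-written clock times. A point-event test demonstrably leaks the tail of
an incident's physiological response into references that start just after
it, biasing paired differences toward zero.

Each retained frame is summarized by the mean over valid samples (movement,
HR, SCL) and PPM; a measure is missing independently when its own source is
fully invalid in the window, and a fully off-wrist window has no wearer, so
every summary is missing. Pairing is at the incident level: incident value
vs the mean of its retained references, one row per incident per measure;
a measure missing on either side drops the row for that measure only.

## Inference

Four hypotheses (movement, HR, SCL, PPM) are tested with paired t tests,
t = mean(d)/(sd(d)/√n) on d = incident − reference-mean, df = n − 1,
two-sided p, at a Bonferroni-adjusted threshold family-alpha/4 (0.05/4 =
0.0125, reported as .013 under half-up rounding). p values print with 3
decimals below .01 and 2 otherwise, matching the reporting style of the
clinical literature this serves. Group means and SDs are reported per side;
they cannot reconstruct the paired statistic and are never used to.
Zero-variance differences raise rather than print an infinite t; a measure
with fewer than 2 pairs is reported as not testable. Holm/FDR alternatives
are deliberately absent from the default path.

## Synthetic cohort generator

The generator emulates the study inputs end to end: clinic children wear
08:00–20:00, daycare 08:00–15:00, five consecutive days; HR baselines are
drawn inside the APLS age norms (80–120 bpm under 12 y, 60–100 bpm from
12 y) away from the band edges; tonic SCL is a per-child base (1–8 µS) plus
a slow drift (OU process, sd 0.5 µS, time constant 1800 s, generated on a
coarse grid and band-limited — tonic EDA varies on the tens-of-minutes
scale, and high-frequency power in the "tonic" component would masquerade as
phasic activity); SCRs are Bateman-kernel bumps (rise 0.75 s, decay 3 s,
lognormal amplitudes around 0.3 µS) at 2.6/min — the scale of the study's
reference-episode PPM — with a 4 s inter-response refractory interval,
because responses closer than that superpose into a single countable peak
for any trough-to-peak detector. HR is AR(1) (sd 6 bpm, time constant
200 s). Movement is gravity plus noise plus Poisson bursts. Off-wrist spans
(12–40 min) zero the EDA, decay temperature toward ambient and — emulating
the device — replace HR with plausible-but-wrong 140–170 bpm values, so HR
invalidation is genuinely exercised. Artifact bursts inject high-slope EDA
noise. Sparse valid-IBI segments appear a few times a day.

Red incidents (default 2/child-day, ≥ 600 s apart, onsets on whole minutes —
observers write clock times, and minute-grid onsets keep the recorded time
equal to the true effect onset) add a boxcar +9 bpm HR shift, a ramped
+0.15 µS SCL shift (tonic rises are gradual; a step edge would be a phasic
artifact), +0.6/min extra SCRs and a small movement oscillation over the
5-minute window. Orange events are logged but carry no physiological effect
by default — disruptive behavior with and without an arousal response both
occur, and the vignette days script exactly that. Seeded runs are
bit-reproducible.

What the generator does *not* emulate: diagnosis-specific physiology,
posture/pressure EDA artifacts with realistic morphology, circadian HR
trends, device drift, or correlated multi-channel artifacts. Passing the
synthetic suite therefore shows the pipeline recovers known effects under
idealized-but-plausible signal statistics; it does not validate the artifact
rules against real wear data.

## Validation experiments and problem sizes

`e4arousal.experiments` fixes two standing experiments (also run by
`scripts/acceptance.py`):

* **Recovery** — 30 children × 5 days with the +9 bpm injection, wearing
  windows shortened to 2 h/day; ≈ 300 usable pairs. Across 10 seeds the
  standardized recovery error has mean 0.13 and sd 1.10: unbiased, with
  honest standard errors.
* **Null calibration** — zero-effect cohorts repeated over 200 seeds, with
  1 red/child-day and 8 children per cohort. Both choices come from a
  variance analysis: packing ≥ 2 incidents into a shortened wearing window
  puts them inside one tonic-drift correlation length and clusters the
  paired differences (an artifact of the scaling, not of the full-length
  study day, where incidents sit hours apart), and ≈ 33 pairs per cohort —
  the df = 32 scale at which the study ran its own tests — is where the t
  approximation holds for the mildly skewed movement differences.

The shortened windows change only the amount of non-incident signal
processed, not the frame procedure, exclusion rules or inference.

## Numerical conventions and degenerate inputs

Quartiles use linear interpolation (type 7). Retention percentages round to
integers, exclusion percentages to one decimal, the Bonferroni threshold to
three decimals half-up. Clock alignment is mean-within-bin with empty bins
missing; a session whose channels share no wall-clock overlap is an error.
An empty day renders an empty dashboard, not an exception. Duplicate
observation rows are kept with a warning (two observer streams may
legitimately double-report); deduplication is an explicit call.

## Known limitations

Incident-level pairing treats incidents from one child as independent, as
the source analysis did; a mixed-effects model is out of scope here. The
off-wrist rule is EDA-led (temperature participates only as an epoch rule);
accelerometer-only wear detection is not implemented. BVP is never
processed. HRV is descriptive only.
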