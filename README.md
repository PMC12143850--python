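# e4arousal

Wearable psychophysiology for behavioral incident analysis in child
psychiatry. Children in clinical or daycare treatment wear a wrist biosensor
(Empatica-E4-style raw export: EDA, skin temperature, triaxial acceleration,
BVP, device-derived HR, inter-beat intervals) for five consecutive days while
staff log behavior on a traffic-light scale — green (good behavior), orange
(disruptive), red (physical aggression / severe disruption). `e4arousal`
turns those two inputs into the question clinicians actually ask: *do
physiological arousal measures differ during aggressive incidents compared
with matched calm moments of the same child?*

The pipeline:

1. **Ingest** raw session directories/zips onto a common UTC clock
   (`e4arousal.e4io`), with ACC counts converted at 1/64 g.
2. **Quality-mask** the EDA on 5 s epochs by rule (range, slope, skin
   temperature), separate in-signal **artifacts** from ≥10-minute
   **off-wrist** spans, and blank the device HR inside off-wrist spans —
   the device otherwise reports an artificially high HR while unworn
   (`e4arousal.quality`).
3. **Derive measures** (`e4arousal.features`): movement in g
   (gravity-removed acceleration magnitude), tonic SCL in µS (30 s moving
   average over valid samples), SCR **peaks per minute** on the phasic
   component, and RMSSD from consecutive inter-beat intervals (displayed,
   not tested — valid IBI is too sparse at the wrist).
4. **Frame extraction** (`e4arousal.frames`): a 5-minute frame at each red
   incident's recorded onset, paired with same-clock-time reference frames
   from the child's other wearing days; references overlapping aggression
   episodes are excluded, as is any frame with more than 75% EDA artifacts.
5. **Inference** (`e4arousal.stats`): paired t tests on
   d = incident − reference-mean for movement, HR, SCL and PPM, at the
   Bonferroni-adjusted threshold α/4 (0.05/4 = 0.0125, reported as .013):

   t = mean(d) / (sd(d)/√n),  df = n − 1,  p = 2·(1 − F_t(|t|; df)).

A synthetic cohort generator (`e4arousal.synth`) emulates both input kinds —
tonic SCL drift, Bateman-kernel SCRs, pediatric-norm HR, motion bursts,
off-wrist dropouts with spurious HR, and arousal effects co-timed with red
incidents — so the whole pipeline is testable against known ground truth,
and `e4arousal.report` renders the five-panel clinical dashboard (movement,
temperature, SCL with event marks, HR, HRV) plus cohort retention and
collection summaries.

## Worked example

Simulate a small cohort with a known +9 bpm HR shift during red incidents
and run the full analysis:

```python
from e4arousal.synth import SyntheticConfig
from e4arousal.pipeline import run_cohort_analysis

cfg = SyntheticConfig(n_participants=6, days=5,
                      clinic_hours=(8.0, 11.0), daycare_hours=(8.0, 11.0),
                      include_bvp=False)
res = run_cohort_analysis(cfg, seed=17)
print(res.analysis.table()[["measure", "n_pairs", "mean_incident", "mean_reference",
                            "t", "df", "p_printed", "significant"]].round(3).to_string(index=False))
hr = res.mean_paired_difference("hr_bpm")
print("\nrecovered HR shift: %.2f bpm (SE %.2f, n=%d); injected: +9 bpm" % hr)
```

prints

```
   measure  n_pairs  mean_incident  mean_reference     t  df p_printed  significant
movement_g       45          0.089           0.075 1.746  44       .09        False
    hr_bpm       45         99.892          91.909 9.355  44     <.001         True
    scl_uS       45          3.673           3.583 1.147  44       .26        False
       ppm       45          2.769           2.352 3.810  44     <.001         True

recovered HR shift: 7.98 bpm (SE 0.85, n=45); injected: +9 bpm
```

Each row is one paired hypothesis: 45 red incidents each compared with the
mean of that child's same-clock-time reference windows. The injected HR and
PPM effects are detected at the adjusted threshold; SCL and movement (given
only small injected shifts) are not — the same decision pattern the method
is designed to resolve on real data. The recovered mean paired HR difference
is within two standard errors of the +9 bpm ground truth.

The same stages are scriptable from a shell:

```sh
e4arousal simulate --seed 17 --out cohort/
e4arousal frames --sessions cohort/ --observations cohort/observations.csv \
    --tz Europe/Amsterdam --out results/run1
e4arousal report --session cohort/P01_day1 --observations cohort/observations.csv \
    --tz Europe/Amsterdam --out day1.html --png day1.png
```

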