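"""Cohort-level validation experiments on synthetic data.

Two standing experiments verify the pipeline end to end:

* **Parameter recovery** — a cohort of 30 children over 5 days with a known
  +9 bpm HR shift injected during red incidents (≈2 per child-day); the
  pipeline's mean paired HR difference must agree with the injected shift
  within Monte-Carlo error.
* **Null calibration** — the same pipeline on cohorts with zero injected
  effects, repeated over many seeds; the per-test rejection rate at the
  Bonferroni-adjusted alpha (.05/4 = 0.0125) must match the nominal level.

Both experiments use shortened wearing windows (2 h and 1.5 h per day instead
of the full 7–12 h) so that hundreds of full pipeline runs stay cheap; the
frame procedure, exclusion rules and inference are identical to the full-day
path, and incident density per recorded hour is what drives the statistics.
"""

from __future__ import annotations

import numpy as np

from .frames import MEASURES
from .pipeline import CohortResult, run_cohort_analysis
from .stats import bonferroni_alpha
from .synth import SyntheticConfig

__all__ = ["RECOVERY_CONFIG", "NULL_CONFIG", "recovery_experiment", "null_calibration"]

#: recovery cohort: full study width (30 children, 5 days, ~2 red/child-day,
#: +9 bpm injected), shortened wearing window
RECOVERY_CONFIG = SyntheticConfig(
    n_participants=30,
    days=5,
    clinic_hours=(8.0, 10.0),
    daycare_hours=(8.0, 10.0),
    include_bvp=False,
)

#: null cohort: zero injected effects, small and fast enough to repeat x200.
#: One red incident per child-day: in the full-length study day incidents are
#: hours apart and their slow-drift components decorrelate, but a shortened
#: wearing window would push multiple incidents inside one tonic-drift
#: correlation length and cluster the paired differences — an artifact of the
#: scaling, not of the design the calibration is meant to check.  Eight
#: children give ≈33 usable pairs per cohort — the sample size at which the
#: study itself ran its paired tests, and enough for the t approximation to
#: hold for the mildly skewed movement differences.
NULL_CONFIG = SyntheticConfig(
    n_participants=8,
    days=5,
    clinic_hours=(8.0, 9.5),
    daycare_hours=(8.0, 9.5),
    red_per_day=1.0,
    orange_per_day=1.0,
    effect_hr_bpm=0.0,
    effect_scl_uS=0.0,
    effect_ppm=0.0,
    effect_movement_g=0.0,
    include_bvp=False,
)


def recovery_experiment(seed: int, config: SyntheticConfig | None = None) -> dict:
    """Run the injected-effect cohort and report recovered paired differences."""
    cfg = config or RECOVERY_CONFIG
    result: CohortResult = run_cohort_analysis(cfg, seed)
    out: dict = {"seed": seed}
    for measure, injected in (
        ("hr_bpm", cfg.effect_hr_bpm),
        ("ppm", cfg.effect_ppm),
        ("scl_uS", cfg.effect_scl_uS),
    ):
        mean_d, se, n = result.mean_paired_difference(measure)
        out[measure] = {
            "injected": injected,
            "recovered_mean_difference": mean_d,
            "standard_error": se,
            "n_pairs": n,
        }
    out["exclusions"] = result.analysis.exclusions
    return out


def null_calibration(
    seed: int, n_seeds: int = 200, config: SyntheticConfig | None = None
) -> dict:
    """Type-I-error check: rejection rates under the zero-effect generator.

    Runs ``n_seeds`` independent null cohorts (child seeds derived from
    ``seed``) and counts, per measure and pooled, how often the paired test
    rejects at the Bonferroni-adjusted threshold.  Reports the Monte-Carlo
    standard deviation of the pooled estimate at the nominal rate.
    """
    cfg = config or NULL_CONFIG
    alpha = bonferroni_alpha(0.05, len(MEASURES)).exact
    rejections = {m: 0 for m in MEASURES}
    tests = {m: 0 for m in MEASURES}
    child_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for s in child_seeds:
        result = run_cohort_analysis(cfg, int(s))
        for r in result.analysis.results:
            if r.testable:
                tests[r.measure] += 1
                rejections[r.measure] += bool(r.significant)
    pooled_tests = sum(tests.values())
    pooled_rej = sum(rejections.values())
    rate = pooled_rej / pooled_tests if pooled_tests else float("nan")
    return {
        "seed": seed,
        "n_seeds": n_seeds,
        "alpha_adjusted": alpha,
        "per_measure_rate": {
            m: (rejections[m] / tests[m] if tests[m] else float("nan")) for m in MEASURES
        },
        "pooled_rejection_rate": rate,
        "pooled_tests": pooled_tests,
        "mc_sd_at_nominal": float(np.sqrt(alpha * (1 - alpha) / pooled_tests))
        if pooled_tests
        else float("nan"),
    }
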