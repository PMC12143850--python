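"""Paired-sample inference with Bonferroni correction.

Four hypotheses are tested (movement, HR, SCL, PPM), each with a paired
t test of incident values against the mean of their within-person matched
references, at a Bonferroni-adjusted alpha of family_alpha / 4 (.05/4 =
0.0125, reported as .013).

t = mean(d) / (sd(d) / sqrt(n)) on d = incident − reference_mean, with
df = n − 1 and a two-sided p from the t distribution.  Group means and SDs
are reported per side; they cannot reconstruct the paired statistic (which
depends on the SD of the *differences*) and neither is ever back-derived
from the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

from .frames import MEASURES

__all__ = [
    "BonferroniAlpha",
    "PairedComparisonResult",
    "bonferroni_alpha",
    "paired_t",
    "t_p_value",
    "format_p",
    "run_family",
]


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BonferroniAlpha:
    exact: float
    rounded: float  # 3 decimals, half-up — the reporting convention


def bonferroni_alpha(family_alpha: float, n_tests: int) -> BonferroniAlpha:
    """Per-test threshold family_alpha / n_tests, with its 3-decimal report."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    exact = family_alpha / n_tests
    return BonferroniAlpha(exact=exact, rounded=_round_half_up(exact, 3))


def t_p_value(t: float, df: int) -> float:
    """Exact two-sided tail probability 2·(1 − F_t(|t|; df))."""
    if df < 1:
        raise ValueError("df must be at least 1")
    return float(2.0 * sps.t.sf(abs(t), df))


def format_p(p: float) -> str:
    """Render p the way the results tables print it: 3 decimals below .01,
    2 decimals otherwise, without a leading zero (.007, .07, .33); values that
    would round to zero print as <.001."""
    if p < 0.0005:
        return "<.001"
    nd = 3 if p < 0.01 else 2
    s = f"{_round_half_up(p, nd):.{nd}f}"
    return s[1:] if s.startswith("0.") else s


@dataclass
class PairedComparisonResult:
    measure: str
    n_pairs: int
    mean_incident: float
    sd_incident: float
    mean_reference: float
    sd_reference: float
    mean_difference: float
    sd_difference: float
    t_statistic: float
    df: int
    p_two_sided: float
    alpha_adjusted: float
    significant: bool | None  # None when not testable (n_pairs < 2)

    @property
    def testable(self) -> bool:
        return self.significant is not None

    @property
    def p_formatted(self) -> str:
        return format_p(self.p_two_sided) if self.testable else "n/a"


def paired_t(
    incident: np.ndarray,
    reference: np.ndarray,
    measure: str = "hr_bpm",
    alpha_adjusted: float = 0.05,
) -> PairedComparisonResult:
    """Paired t test of incident vs matched-reference values.

    Degenerate inputs — all differences identical — leave the statistic
    undefined and raise rather than reporting an infinite t.
    """
    incident = np.asarray(incident, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if incident.shape != reference.shape:
        raise ValueError("paired sides must have equal length")
    n = len(incident)
    if n < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = incident - reference
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0.0:
        raise ZeroDivisionError("differences have zero variance; t undefined")
    t = float(np.mean(d) / (sd_d / np.sqrt(n)))
    df = n - 1
    return PairedComparisonResult(
        measure=measure,
        n_pairs=n,
        mean_incident=float(np.mean(incident)),
        sd_incident=float(np.std(incident, ddof=1)),
        mean_reference=float(np.mean(reference)),
        sd_reference=float(np.std(reference, ddof=1)),
        mean_difference=float(np.mean(d)),
        sd_difference=sd_d,
        t_statistic=t,
        df=df,
        p_two_sided=t_p_value(t, df),
        alpha_adjusted=alpha_adjusted,
        significant=t_p_value(t, df) < alpha_adjusted,
    )


def _untestable(measure: str, n: int, alpha: float) -> PairedComparisonResult:
    nan = float("nan")
    return PairedComparisonResult(
        measure, n, nan, nan, nan, nan, nan, nan, nan, max(n - 1, 0), nan, alpha, None
    )


def run_family(
    tables: dict[str, pd.DataFrame],
    family_alpha: float = 0.05,
    measures: tuple[str, ...] = MEASURES,
) -> list[PairedComparisonResult]:
    """Run the full hypothesis family with a shared Bonferroni threshold.

    ``tables`` maps measure → DataFrame with ``incident``/``reference``
    columns (as produced by :func:`e4arousal.frames.assemble_pairs`).  A
    measure with fewer than 2 pairs is reported as not testable, never as an
    exception; the adjusted alpha always divides by the *family* size.
    """
    alpha = bonferroni_alpha(family_alpha, len(measures)).exact
    results = []
    for m in measures:
        tab = tables.get(m)
        if tab is None or len(tab) < 2:
            results.append(_untestable(m, 0 if tab is None else len(tab), alpha))
            continue
        try:
            results.append(
                paired_t(tab["incident"].to_numpy(), tab["reference"].to_numpy(), m, alpha)
            )
        except ZeroDivisionError:
            results.append(_untestable(m, len(tab), alpha))
    return results


def family_table(results: list[PairedComparisonResult]) -> pd.DataFrame:
    """Reporting layout: means, SDs, t, df, p (printed style) and decision."""
    return pd.DataFrame(
        [
            {
                "measure": r.measure,
                "n_pairs": r.n_pairs,
                "mean_incident": r.mean_incident,
                "sd_incident": r.sd_incident,
                "mean_reference": r.mean_reference,
                "sd_reference": r.sd_reference,
                "t": r.t_statistic,
                "df": r.df,
                "p": r.p_two_sided,
                "p_printed": r.p_formatted,
                "alpha_adjusted": r.alpha_adjusted,
                "significant": r.significant,
            }
            for r in results
        ]
    )
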