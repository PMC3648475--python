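"""Two-sample comparison of the wet and dry sets, trait by trait.

Pooled (Student) two-sample t-tests, computable either from raw
accession-level values or directly from printed summary statistics
(mean, SD, n per set).  With equal group sizes the pooled statistic is

    t = (mean_dry - mean_wet) / sqrt(sd_wet^2/n + sd_dry^2/n),  df = 2n - 2,

and the two paths agree algebraically whenever the summaries are computed
from the raw data.  Significance is reported in the conventional tiers
ns / * / ** / *** (p >= 0.05 / < 0.05 / < 0.01 / < 0.001).  A Shapiro-Wilk
normality screen is reported alongside raw-data tests but never blocks the
t-test.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SchemaError
from .reference import ANALYSIS_VARIABLES, SET_N, TRAIT_SUMMARY


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample SD and accession count for one trait in one set."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("sd must be non-negative")
        if self.n < 2:
            raise DomainError("n must be >= 2")


@dataclass(frozen=True)
class TTestResult:
    trait: str
    mean_wet: float
    mean_dry: float
    difference: float  # dry - wet
    t: float
    df: int
    p: float
    tier: str  # ns / * / ** / ***
    shapiro_p_wet: float | None = None
    shapiro_p_dry: float | None = None


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pooled_t_from_summary(
    wet: SummaryStats, dry: SummaryStats, trait: str = ""
) -> TTestResult:
    """Pooled two-sample t-test from per-set summary statistics.

    Uses the classical pooled-variance form, which for equal n reduces to
    ``diff / sqrt(sd_wet^2/n + sd_dry^2/n)``.  Degenerate case: both SDs
    zero and equal means gives t = 0.
    """
    df = wet.n + dry.n - 2
    diff = dry.mean - wet.mean
    sp2 = ((wet.n - 1) * wet.sd**2 + (dry.n - 1) * dry.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / wet.n + 1.0 / dry.n))
    if se == 0:
        if diff == 0:
            t = 0.0
        else:
            raise DomainError("zero variance with unequal means: t undefined")
    else:
        t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(
        trait=trait,
        mean_wet=wet.mean,
        mean_dry=dry.mean,
        difference=diff,
        t=float(t),
        df=int(df),
        p=float(p),
        tier=significance_tier(p),
    )


def pooled_t_from_raw(
    wet_values: Sequence[float], dry_values: Sequence[float], trait: str = ""
) -> TTestResult:
    """Pooled t-test from raw accession means, with a normality screen.

    Identical to :func:`pooled_t_from_summary` applied to the computed
    summaries (sample SD, ddof=1).  Shapiro-Wilk p-values per set are
    attached for reporting; the test proceeds regardless of the screen.
    """
    x = np.asarray(wet_values, dtype=float)
    y = np.asarray(dry_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DomainError("each set needs at least 2 values")
    res = pooled_t_from_summary(
        SummaryStats(float(x.mean()), float(x.std(ddof=1)), x.size),
        SummaryStats(float(y.mean()), float(y.std(ddof=1)), y.size),
        trait=trait,
    )
    sw = []
    for v in (x, y):
        if np.ptp(v) == 0:
            sw.append(float("nan"))  # Shapiro undefined for constant samples
        else:
            sw.append(float(stats.shapiro(v).pvalue))
    return TTestResult(
        **{**res.__dict__, "shapiro_p_wet": sw[0], "shapiro_p_dry": sw[1]}
    )


def comparison_table(
    wet_traits: pd.DataFrame,
    dry_traits: pd.DataFrame,
    variables: Sequence[str] = ANALYSIS_VARIABLES,
) -> pd.DataFrame:
    """One pooled t-test row per analysis variable (canonical order).

    Inputs are accession-level trait tables (one row per accession) for
    each set; the difference column is dry minus wet.
    """
    if wet_traits.empty or dry_traits.empty:
        raise DomainError("both trait tables must be non-empty")
    rows = []
    for var in variables:
        if var not in wet_traits.columns or var not in dry_traits.columns:
            raise SchemaError(f"trait column missing from input: {var}")
        res = pooled_t_from_raw(
            wet_traits[var].to_numpy(), dry_traits[var].to_numpy(), trait=var
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def reference_comparison_table() -> pd.DataFrame:
    """t-tests recomputed from the bundled reference summary statistics.

    One row per analysis variable, including the originally reported t for
    side-by-side comparison (``published_t``) and whether that value is
    recoverable from the printed summaries (``t_reproducible``).
    """
    rows = []
    for var in ANALYSIS_VARIABLES:
        s = TRAIT_SUMMARY[var]
        res = pooled_t_from_summary(
            SummaryStats(s.wet_mean, s.wet_sd, SET_N),
            SummaryStats(s.dry_mean, s.dry_sd, SET_N),
            trait=var,
        )
        row = res.__dict__.copy()
        row["published_t"] = s.published_t
        row["t_reproducible"] = s.t_reproducible
        rows.append(row)
    return pd.DataFrame(rows)
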