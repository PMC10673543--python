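"""Cohort-level efficacy statistics for preclinical tumor studies.

Covers the standard readouts of a two-arm (or k-arm) treatment study:
caliper tumor volume (V = A * B^2 / 2), pooled-variance unpaired t-tests
(including the summary-statistic form that reproduces printed mean +- SD
comparisons exactly), one- and two-way ANOVA with Bonferroni-adjusted
pairwise comparisons, the Shapiro-Wilk normality check, and Kaplan-Meier
survival with a log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStat",
    "TTestResult",
    "tumor_volume",
    "t_test_from_summary",
    "t_test",
    "summarize",
    "anova_bonferroni",
    "anova_two_way",
    "shapiro_wilk",
    "km_survival",
    "validate_cohort_table",
]

COHORT_COLUMNS = [
    "animal_id", "group", "day", "diameter_A", "diameter_B",
    "body_weight", "event_time", "event_flag",
]


@dataclass(frozen=True)
class SummaryStat:
    """Printed group summary: mean +- SD with group size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2 for testing")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def tumor_volume(A: float, B: float) -> float:
    """Caliper tumor volume V = A * B^2 / 2 (mm^3).

    A is the longest and B the shortest of the two perpendicular
    diameters; the formula approximates an ellipsoid of revolution.
    """
    if B < 0 or A < B:
        raise ValueError("diameters must satisfy A >= B >= 0")
    return A * B * B / 2.0


def summarize(sample: Sequence[float], label: str = "") -> SummaryStat:
    x = np.asarray(sample, dtype=float)
    return SummaryStat(label, float(x.mean()), float(x.std(ddof=1)), int(x.size))


def t_test_from_summary(g1: SummaryStat, g2: SummaryStat) -> TTestResult:
    """Classic pooled-variance unpaired Student t from group summaries.

    df = n1 + n2 - 2; two-sided p.  Exactly recomputable from printed
    mean +- SD values, which is how published group comparisons are
    checked here.  Degenerate zero-variance input: equal means give
    t = 0, p = 1; unequal means are rejected (t undefined).
    """
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return TTestResult(0.0, g1.n + g2.n - 2, 1.0)
        raise ZeroDivisionError(
            "zero pooled variance with unequal means: t statistic undefined"
        )
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return TTestResult(float(t), g1.n + g2.n - 2, float(p))


def t_test(x1: Sequence[float], x2: Sequence[float], welch: bool = False) -> TTestResult:
    """Unpaired t on raw samples (pooled Student by default, Welch optional)."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    res = stats.ttest_ind(x1, x2, equal_var=not welch)
    df = x1.size + x2.size - 2 if not welch else int(np.floor(res.df))
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def anova_bonferroni(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    comparisons: Sequence[tuple[int, int]] | None = None,
) -> dict:
    """One-way ANOVA plus Bonferroni-adjusted pairwise Student t-tests.

    Adjusted p = min(1, m * p_raw) with m the number of comparisons (pure
    alpha splitting, no step-down).  Default comparisons: all pairs.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    labels = list(labels) if labels else [f"g{i}" for i in range(len(arrays))]
    F, p = stats.f_oneway(*arrays)
    if comparisons is None:
        comparisons = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    m = len(comparisons)
    pairs = []
    for i, j in comparisons:
        r = t_test(arrays[i], arrays[j])
        pairs.append(
            dict(pair=(labels[i], labels[j]), t=r.t, df=r.df,
                 p_raw=r.p, p_adj=min(1.0, m * r.p))
        )
    return {"F": float(F), "p": float(p), "comparisons": pairs}


def anova_two_way(
    df: pd.DataFrame, dv: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Two-factor ANOVA with interaction (e.g. treatment group x time).

    Returns the statsmodels type-II ANOVA table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols(f"{dv} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000."""
    x = np.asarray(sample, float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the longitudinal cohort table invariants; returns the table.

    Raises a ValueError naming the first offending row (1-based, counting
    the header) on malformed input.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    for idx, row in table.iterrows():
        line = idx + 2
        try:
            a, b = float(row.diameter_A), float(row.diameter_B)
            day = float(row.day)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"cohort table line {line}: non-numeric field") from exc
        if a < b:
            raise ValueError(
                f"cohort table line {line}: diameter_A ({a}) < diameter_B ({b})"
            )
        if day < 0:
            raise ValueError(f"cohort table line {line}: negative day {day}")
    return table


def km_survival(table: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per group and a two-group log-rank test.

    ``table`` needs one row per animal-day (or per animal) with columns
    animal_id, group, event_time, event_flag; per-animal values are
    deduplicated.  With every animal of a group censored the curves are
    still returned and the test is flagged unstable.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    per_animal = (
        table[["animal_id", "group", "event_time", "event_flag"]]
        .drop_duplicates("animal_id")
        .reset_index(drop=True)
    )
    curves = {}
    unstable = False
    for group, sub in per_animal.groupby("group"):
        km = KaplanMeierFitter(label=str(group))
        km.fit(sub.event_time, event_observed=sub.event_flag.astype(bool))
        curves[group] = km
        if not sub.event_flag.astype(bool).any():
            unstable = True
    groups = sorted(curves)
    if len(groups) == 2:
        g1 = per_animal[per_animal.group == groups[0]]
        g2 = per_animal[per_animal.group == groups[1]]
        res = logrank_test(
            g1.event_time, g2.event_time,
            event_observed_A=g1.event_flag.astype(bool),
            event_observed_B=g2.event_flag.astype(bool),
        )
    else:
        res = multivariate_logrank_test(
            per_animal.event_time, per_animal.group, per_animal.event_flag.astype(bool)
        )
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "unstable": unstable,
    }
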