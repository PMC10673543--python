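"""Human-readable and TSV statistics reports for cohort studies.

Two entry points:

* ``summary_report`` -- pairwise pooled t-tests computed directly from
  printed group summaries (measure, group, mean, sd, n), the form in which
  published group comparisons are stated.
* ``cohort_report`` -- longitudinal caliper-volume comparisons (two-way
  group x day ANOVA with Bonferroni per-day contrasts, or per-day t-tests),
  Kaplan-Meier survival with log-rank, and optional per-animal imaging
  endpoints (mean pHe, acidity score) by week.
"""

from __future__ import annotations

import pandas as pd

from . import cohortstats as cs

__all__ = ["summary_report", "cohort_report", "format_report"]


def summary_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Pairwise pooled t-tests from a printed-summary table.

    ``summary`` columns: measure, group, mean, sd, n.  For every measure,
    every pair of groups is compared with the classic pooled Student t.
    """
    for col in ("measure", "group", "mean", "sd", "n"):
        if col not in summary.columns:
            raise ValueError(f"summary table lacks column {col!r}")
    rows = []
    for measure, sub in summary.groupby("measure", sort=False):
        stats_by_group = [
            cs.SummaryStat(str(r.group), float(r["mean"]), float(r.sd), int(r.n))
            for _, r in sub.iterrows()
        ]
        for i in range(len(stats_by_group)):
            for j in range(i + 1, len(stats_by_group)):
                g1, g2 = stats_by_group[i], stats_by_group[j]
                res = cs.t_test_from_summary(g1, g2)
                rows.append(
                    dict(
                        measure=measure, group_1=g1.label, group_2=g2.label,
                        mean_1=g1.mean, sd_1=g1.sd, n_1=g1.n,
                        mean_2=g2.mean, sd_2=g2.sd, n_2=g2.n,
                        test="pooled t", t=res.t, df=res.df, p=res.p,
                    )
                )
    return pd.DataFrame(rows)


def cohort_report(
    table: pd.DataFrame,
    endpoint_table: pd.DataFrame | None = None,
    volume_comparison: str = "two_way_anova",
) -> dict:
    """Full efficacy report on a longitudinal cohort table.

    Returns a dict with 'volume' (per-day group contrasts), 'anova'
    (two-way table when requested), 'survival' (log-rank), and 'endpoints'
    (per-week t-tests on imaging endpoints when provided).
    """
    cs.validate_cohort_table(table)
    tab = table.copy()
    tab["volume"] = [
        cs.tumor_volume(a, b) for a, b in zip(tab.diameter_A, tab.diameter_B)
    ]
    groups = sorted(tab.group.unique())
    out: dict = {"volume_comparison": volume_comparison}

    rows = []
    days = sorted(tab.day.unique())
    if len(groups) == 2:
        per_day_p = []
        for day in days:
            sub = tab[tab.day == day]
            s = [sub[sub.group == g].volume.to_numpy() for g in groups]
            if min(len(x) for x in s) < 2:
                continue
            res = cs.t_test(s[0], s[1])
            per_day_p.append(res.p)
            rows.append(
                dict(day=day, group_1=groups[0], group_2=groups[1],
                     mean_1=s[0].mean(), sd_1=s[0].std(ddof=1),
                     mean_2=s[1].mean(), sd_2=s[1].std(ddof=1),
                     test="pooled t", t=res.t, df=res.df, p_raw=res.p,
                     p_adj=min(1.0, len(days) * res.p))
            )
    out["volume"] = pd.DataFrame(rows)
    if volume_comparison == "two_way_anova":
        out["anova"] = cs.anova_two_way(tab, "volume", "group", "day")

    out["survival"] = cs.km_survival(tab)

    if endpoint_table is not None and len(groups) == 2:
        ep_rows = []
        value_cols = [
            c for c in endpoint_table.columns
            if c not in ("animal_id", "group", "week", "day")
        ]
        time_col = "week" if "week" in endpoint_table.columns else "day"
        for col in value_cols:
            for t, sub in endpoint_table.groupby(time_col):
                s = [sub[sub.group == g][col].dropna().to_numpy() for g in groups]
                if min(len(x) for x in s) < 2:
                    continue
                res = cs.t_test(s[0], s[1])
                ep_rows.append(
                    dict(endpoint=col, **{time_col: t},
                         group_1=groups[0], group_2=groups[1],
                         mean_1=s[0].mean(), sd_1=s[0].std(ddof=1),
                         mean_2=s[1].mean(), sd_2=s[1].std(ddof=1),
                         test="pooled t", t=res.t, df=res.df, p=res.p)
                )
        out["endpoints"] = pd.DataFrame(ep_rows)
    return out


def format_report(report: dict) -> str:
    """Plain-text rendering of a cohort_report result."""
    lines = []
    vol = report.get("volume")
    if vol is not None and len(vol):
        lines.append("Tumor volume, per-day group contrasts "
                     f"({report.get('volume_comparison')}):")
        for _, r in vol.iterrows():
            lines.append(
                f"  day {r.day:>4.0f}: {r.group_1} {r.mean_1:8.1f}+-{r.sd_1:6.1f} vs "
                f"{r.group_2} {r.mean_2:8.1f}+-{r.sd_2:6.1f} mm^3  "
                f"t={r.t:6.2f} df={r.df:.0f} p={r.p_raw:.3g} p_adj={r.p_adj:.3g}"
            )
    if "anova" in report:
        lines.append("\nTwo-way ANOVA (group x day):")
        lines.append(report["anova"].to_string())
    surv = report.get("survival")
    if surv:
        flag = "  [unstable: all-censored group]" if surv["unstable"] else ""
        lines.append(f"\nLog-rank test: chi2={surv['statistic']:.3f} "
                     f"p={surv['p']:.4g}{flag}")
    ep = report.get("endpoints")
    if ep is not None and len(ep):
        lines.append("\nImaging endpoints:")
        time_col = "week" if "week" in ep.columns else "day"
        for _, r in ep.iterrows():
            lines.append(
                f"  {r.endpoint} {time_col} {r[time_col]}: "
                f"{r.group_1} {r.mean_1:.3f}+-{r.sd_1:.3f} vs "
                f"{r.group_2} {r.mean_2:.3f}+-{r.sd_2:.3f}  "
                f"t={r.t:6.2f} p={r.p:.3g}"
            )
    return "\n".join(lines)
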