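"""Cohort-level aggregation: group means with t-based 95% CIs and paired
interval/compartment comparisons, rendered as tidy tables.

The comparisons are paired two-sided t-tests on within-subject differences
(every compartment and both dosing intervals are measured in every subject).
This is a deliberate simplification of a mixed-model ANOVA with
small-sample degrees-of-freedom correction and is flagged as such in the
table-set metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study import COMPARTMENTS


class SummaryError(ValueError):
    pass


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    ci_low: float    # nan when n == 1
    ci_high: float


def group_mean_ci(values: Sequence[float], level: float = 0.95,
                  label: str = "") -> GroupSummary:
    """Arithmetic mean with a t-distribution confidence interval.

    CI = mean ± t_{n−1, 1−α/2} · sd/√n; undefined (nan bounds) when n = 1.
    """
    vals = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    n = vals.size
    if n == 0:
        raise SummaryError("cannot summarize an empty group")
    if not 0 < level < 1:
        raise SummaryError(f"confidence level must be in (0,1), got {level}")
    mean = float(vals.mean())
    if n == 1:
        return GroupSummary(label, 1, mean, float("nan"), float("nan"), float("nan"))
    sd = float(vals.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2, n - 1) * sd / math.sqrt(n)
    return GroupSummary(label, n, mean, sd, mean - half, mean + half)


def compare_intervals(values_1: Sequence[float], values_2: Sequence[float]) -> float:
    """Two-sided paired t-test p-value on within-subject differences.

    Pairs containing a missing value are dropped; all-zero differences give
    p = 1.0 (no evidence of any interval effect).
    """
    pairs = [(a, b) for a, b in zip(values_1, values_2)
             if a is not None and b is not None
             and not (np.isnan(a) or np.isnan(b))]
    if len(pairs) < 2:
        raise SummaryError(f"paired comparison needs >= 2 complete pairs, got {len(pairs)}")
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return 1.0 if np.allclose(diff, 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def _pivot(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """subject × interval wide layout for one metric column."""
    return df.pivot_table(index="subject_id", columns="interval", values=value,
                          aggfunc="first")


def _summary_row(label: str, values, level: float) -> dict:
    g = group_mean_ci(values, level, label)
    return {"n": g.n, "mean": g.mean, "sd": g.sd, "ci_low": g.ci_low, "ci_high": g.ci_high}


def summarize_cohort(nca_df: pd.DataFrame, pd_df: pd.DataFrame,
                     weights: pd.DataFrame | None = None,
                     level: float = 0.95,
                     interval_length: float = 480.0) -> dict:
    """Render the four report tables from per-subject NCA and PD results.

    ``weights`` (subject_id, weight_kg, weight_group) enables the per-weight-
    group table; without it that table is empty.  Returns a dict with tables
    1–4 as tidy DataFrames plus a metadata dict.  Subjects missing a metric
    keep a flagged (NaN) row rather than being dropped.
    """
    warnings: list[str] = []

    # penetration per subject × interval
    auc_wide = nca_df.pivot_table(index=["subject_id", "interval"], columns="compartment",
                                  values="auc", aggfunc="first").reset_index()
    for comp in ("deadspace", "bone"):
        if comp in auc_wide:
            auc_wide[f"pen_{comp}"] = auc_wide[comp] / auc_wide["plasma"]

    # ---- Table 2: fT>MIC minutes and % per compartment × interval + totals
    t2_rows, t2_comparisons = [], []
    ft_totals: dict[str, pd.Series] = {}
    for comp in COMPARTMENTS:
        sub = pd_df[pd_df.compartment == comp]
        wide_min = _pivot(sub, "t_above_mic")
        wide_pct = _pivot(sub, "pct_above_mic")
        if wide_min.empty:
            warnings.append(f"no PD results for compartment {comp}")
            continue
        total = wide_min.sum(axis=1)
        ft_totals[comp] = total
        for metric, wide in (("ft_min", wide_min), ("ft_pct", wide_pct)):
            for itv in wide.columns:
                t2_rows.append({"compartment": comp, "metric": metric,
                                "interval": str(itv),
                                **_summary_row(f"{comp} {metric} {itv}", wide[itv], level)})
        t2_rows.append({"compartment": comp, "metric": "ft_min", "interval": "total",
                        **_summary_row(f"{comp} ft_min total", total, level)})
        t2_rows.append({"compartment": comp, "metric": "ft_pct", "interval": "total",
                        **_summary_row(f"{comp} ft_pct total",
                                       100.0 * total / (2 * interval_length), level)})
        if wide_min.shape[1] >= 2 and wide_min.dropna().shape[0] >= 2:
            cols = list(wide_min.columns)[:2]
            t2_comparisons.append({"compartment": comp, "comparison": "interval_1_vs_2",
                                   "p_value": compare_intervals(wide_min[cols[0]],
                                                                wide_min[cols[1]])})
    for a, b in (("deadspace", "plasma"), ("deadspace", "bone"), ("bone", "plasma")):
        if a in ft_totals and b in ft_totals:
            joined = pd.concat([ft_totals[a], ft_totals[b]], axis=1, keys=[a, b]).dropna()
            if joined.shape[0] >= 2:
                t2_comparisons.append({"compartment": f"{a}_vs_{b}",
                                       "comparison": "total_ft",
                                       "p_value": compare_intervals(joined[a], joined[b])})

    # ---- Table 3: time-to-threshold mean (SD) per compartment × interval
    t3_rows = []
    for comp in COMPARTMENTS:
        wide = _pivot(pd_df[pd_df.compartment == comp], "tt_threshold")
        if wide.empty:
            continue
        if wide.isna().any().any():
            warnings.append(f"{comp}: threshold never reached for some subjects")
        row = {"compartment": comp}
        for itv in wide.columns:
            g = group_mean_ci(wide[itv].dropna(), level)
            row[f"mean_{itv}"] = g.mean
            row[f"sd_{itv}"] = g.sd
            row[f"n_{itv}"] = g.n
        cols = list(wide.columns)
        if len(cols) >= 2 and wide.dropna().shape[0] >= 2:
            complete = wide.dropna()
            row["p_intervals"] = compare_intervals(complete[cols[0]], complete[cols[1]])
        t3_rows.append(row)

    # ---- Table 4: AUC, Cmax, Tmax, T½ and penetration per compartment × interval
    t4_rows = []
    metrics = [("auc", "auc"), ("cmax", "cmax"), ("tmax", "tmax"), ("t_half", "t_half")]
    for comp in COMPARTMENTS:
        sub = nca_df[nca_df.compartment == comp]
        if sub.empty:
            continue
        for metric, col in metrics:
            wide = _pivot(sub, col)
            if wide[wide.columns[0]].isna().any():
                warnings.append(f"{comp} {metric}: undefined for some subjects")
            for itv in wide.columns:
                t4_rows.append({"compartment": comp, "metric": metric, "interval": str(itv),
                                **_summary_row(f"{comp} {metric} {itv}",
                                               wide[itv].dropna(), level)})
            cols = list(wide.columns)
            complete = wide.dropna()
            if len(cols) >= 2 and complete.shape[0] >= 2:
                t4_rows[-1]["p_intervals"] = compare_intervals(complete[cols[0]],
                                                               complete[cols[1]])
    for comp in ("deadspace", "bone"):
        col = f"pen_{comp}"
        if col in auc_wide:
            for itv in sorted(auc_wide["interval"].unique()):
                vals = auc_wide.loc[auc_wide.interval == itv, col].dropna()
                t4_rows.append({"compartment": comp, "metric": "penetration",
                                "interval": str(itv),
                                **_summary_row(f"{comp} penetration {itv}", vals, level)})

    # ---- Table 1: deadspace fT>MIC and penetration per weight group
    t1_rows = []
    if weights is not None and "weight_group" in weights.columns:
        wmap = dict(zip(weights.subject_id, weights.weight_group))
        ds_pd = pd_df[pd_df.compartment == "deadspace"].copy()
        ds_pd["weight_group"] = ds_pd.subject_id.map(wmap)
        pen = auc_wide[["subject_id", "interval", "pen_deadspace"]].copy() \
            if "pen_deadspace" in auc_wide else None
        if pen is not None:
            pen["weight_group"] = pen.subject_id.map(wmap)
        for grp in sorted(set(wmap.values())):
            for itv in sorted(ds_pd["interval"].unique()):
                vals = ds_pd[(ds_pd.weight_group == grp) & (ds_pd.interval == itv)].t_above_mic
                if len(vals):
                    t1_rows.append({"weight_group": grp, "metric": "ft_min",
                                    "interval": str(itv),
                                    **_summary_row(f"{grp} ft {itv}", vals, level)})
                if pen is not None:
                    pvals = pen[(pen.weight_group == grp) & (pen.interval == itv)].pen_deadspace
                    if len(pvals):
                        t1_rows.append({"weight_group": grp, "metric": "penetration",
                                        "interval": str(itv),
                                        **_summary_row(f"{grp} pen {itv}", pvals, level)})

    return {
        "table1_weight_groups": pd.DataFrame(t1_rows),
        "table2_ft_above_mic": pd.DataFrame(t2_rows),
        "table2_comparisons": pd.DataFrame(t2_comparisons),
        "table3_time_to_threshold": pd.DataFrame(t3_rows),
        "table4_pk_parameters": pd.DataFrame(t4_rows),
        "metadata": {
            "statistics": ("paired two-sided t-tests on within-subject differences; "
                           "a deviation from mixed-model ANOVA with small-sample "
                           "df correction"),
            "pct_ft_aggregation": "mean of per-subject percentages",
            "confidence_level": level,
            "warnings": warnings,
        },
    }
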