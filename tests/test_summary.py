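"""Cohort aggregation: t-interval CIs, paired comparisons, table shapes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deadspacepk.summary import (SummaryError, compare_intervals, group_mean_ci,
                                 summarize_cohort)


class TestGroupMeanCi:
    def test_degenerate_equal_values_have_zero_width(self):
        g = group_mean_ci([5.0] * 6)
        assert (g.n, g.mean, g.sd) == (6, 5.0, 0.0)
        assert g.ci_low == g.ci_high == 5.0

    def test_three_values_against_closed_form_t_quantile(self):
        g = group_mean_ci([1.0, 2.0, 3.0], level=0.95)
        half = 4.302652729911275 * 1.0 / math.sqrt(3)  # t_{2, 0.975} · sd/√n
        assert g.mean == 2.0
        assert g.ci_low == pytest.approx(2.0 - half, rel=1e-9)
        assert g.ci_high == pytest.approx(2.0 + half, rel=1e-9)

    def test_single_observation_has_mean_but_no_ci(self):
        g = group_mean_ci([7.5])
        assert g.mean == 7.5 and math.isnan(g.ci_low) and math.isnan(g.ci_high)

    def test_empty_group_raises(self):
        with pytest.raises(SummaryError):
            group_mean_ci([])

    def test_ci_width_shrinks_as_inverse_sqrt_n(self):
        base = [1.0, 2.0, 3.0, 4.0]
        small = group_mean_ci(base * 3)       # n = 12, same sd
        large = group_mean_ci(base * 12)      # n = 48, same sd
        ratio = (small.ci_high - small.ci_low) / (large.ci_high - large.ci_low)
        sd12, sd48 = np.std(base * 3, ddof=1), np.std(base * 12, ddof=1)
        expected = (stats.t.ppf(0.975, 11) * sd12 / math.sqrt(12)) \
            / (stats.t.ppf(0.975, 47) * sd48 / math.sqrt(48))  # ~2·t-correction
        assert ratio == pytest.approx(expected, rel=1e-9)
        assert 1.8 < ratio < 2.4


class TestCompareIntervals:
    def test_identical_pairs_give_p_one(self):
        assert compare_intervals([3.0, 4.0, 5.0], [3.0, 4.0, 5.0]) == 1.0

    def test_constant_shift_with_tiny_spread_is_significant(self):
        a = [10.0, 20.0, 30.0, 40.0]
        b = [v + 10 + e for v, e in zip(a, (0.01, -0.01, 0.02, -0.02))]
        p = compare_intervals(a, b)
        assert p < 0.001
        # independent oracle: t statistic and CDF computed by hand
        d = np.array(a) - np.array(b)
        tstat = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert p == pytest.approx(2 * stats.t.sf(abs(tstat), len(d) - 1), rel=1e-9)

    def test_balanced_differences_give_large_p(self):
        a = [10.0, 20.0, 30.0, 40.0]
        b = [12.0, 18.0, 32.0, 38.0]  # differences ±2 summing to 0
        assert compare_intervals(a, b) > 0.9

    def test_requires_two_complete_pairs(self):
        with pytest.raises(SummaryError):
            compare_intervals([1.0], [2.0])
        with pytest.raises(SummaryError):
            compare_intervals([1.0, float("nan")], [2.0, 3.0])


def _fake_results(n_subjects=6, groups=("53-57 kg",)):
    rng = np.random.default_rng(3)
    sids = [f"pig{i:02d}" for i in range(1, n_subjects + 1)]
    nca_rows, pd_rows, weights = [], [], []
    for i, sid in enumerate(sids):
        weights.append((sid, 55.0, groups[i % len(groups)]))
        for comp, auc0 in (("plasma", 2500), ("deadspace", 4000), ("bone", 1900)):
            for itv in (1, 2):
                auc = auc0 * rng.uniform(0.9, 1.1)
                nca_rows.append((sid, comp, itv, auc, 20.0, 45.0, 0.01, 69.3, 5))
                ft = {"plasma": 130, "deadspace": 300, "bone": 160}[comp] \
                    * rng.uniform(0.9, 1.1)
                pd_rows.append((sid, comp, itv, ft, 100 * ft / 480, 5.0))
    nca = pd.DataFrame(nca_rows, columns=["subject_id", "compartment", "interval",
                                          "auc", "cmax", "tmax", "lambda", "t_half",
                                          "n_lambda_points"])
    pdf = pd.DataFrame(pd_rows, columns=["subject_id", "compartment", "interval",
                                         "t_above_mic", "pct_above_mic", "tt_threshold"])
    w = pd.DataFrame(weights, columns=["subject_id", "weight_kg", "weight_group"])
    return nca, pdf, w


def test_summarize_cohort_table_shapes():
    nca, pdf, w = _fake_results(6, ("53-57 kg", "73-77 kg", "93-97 kg"))
    tables = summarize_cohort(nca, pdf, w)
    t2 = tables["table2_ft_above_mic"]
    # 3 compartments × 2 metrics × (interval 1, interval 2, total)
    assert len(t2) == 18
    assert set(t2.compartment) == {"plasma", "deadspace", "bone"}
    comps = tables["table2_comparisons"]
    assert set(comps.compartment) >= {"plasma", "deadspace", "bone",
                                      "deadspace_vs_plasma", "deadspace_vs_bone",
                                      "bone_vs_plasma"}
    t3 = tables["table3_time_to_threshold"]
    assert len(t3) == 3 and "p_intervals" in t3.columns
    t4 = tables["table4_pk_parameters"]
    # 3 compartments × 4 metrics × 2 intervals + 2 penetration rows × 2 intervals
    assert len(t4) == 28
    t1 = tables["table1_weight_groups"]
    assert set(t1.weight_group) == {"53-57 kg", "73-77 kg", "93-97 kg"}


def test_total_ft_is_mean_of_per_subject_interval_sums():
    nca, pdf, w = _fake_results(6)
    tables = summarize_cohort(nca, pdf, w)
    t2 = tables["table2_ft_above_mic"]
    for comp in ("plasma", "deadspace", "bone"):
        sub = t2[(t2.compartment == comp) & (t2.metric == "ft_min")]
        total = float(sub[sub.interval == "total"]["mean"].iloc[0])
        by_itv = sub[sub.interval != "total"]["mean"].astype(float).sum()
        assert total == pytest.approx(by_itv, rel=1e-12)


def test_single_weight_group_collapses_table1():
    nca, pdf, w = _fake_results(4, ("73-77 kg",))
    t1 = summarize_cohort(nca, pdf, w)["table1_weight_groups"]
    assert set(t1.weight_group) == {"73-77 kg"}


def test_missing_metric_flagged_not_dropped():
    nca, pdf, w = _fake_results(4)
    nca.loc[(nca.subject_id == "pig01") & (nca.interval == 1), "t_half"] = np.nan
    tables = summarize_cohort(nca, pdf, w)
    assert any("t_half" in msg for msg in tables["metadata"]["warnings"])
    t4 = tables["table4_pk_parameters"]
    row = t4[(t4.metric == "t_half") & (t4.interval == "1")]
    assert int(row[row.compartment == "plasma"]["n"].iloc[0]) == 3  # one NaN excluded
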