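"""Non-compartmental metrics: AUC rule, Cmax/Tmax, terminal slope, penetration."""

import math

import numpy as np
import pytest

from deadspacepk.nca import (NcaError, auc_lin_up_log_down, cmax_tmax,
                             compute_nca, half_life, penetration_ratio,
                             terminal_lambda)
from deadspacepk.profiles import ConcProfile
from deadspacepk.study import DoseEvent

from conftest import random_profile
from oracles import auc_fine_grid, ols_slope


def _prof(points):
    t, c = zip(*points)
    return ConcProfile("s", "plasma", np.array(t, float), np.array(c, float))


class TestAucLinUpLogDown:
    def test_linear_rising_segment(self):
        assert auc_lin_up_log_down(_prof([(0, 0), (10, 10)]), 0, 10) == pytest.approx(50.0)

    def test_log_declining_segment_matches_exponential_area(self):
        # area of 10·(1/2)^(t/10) over [0,10] = 5/ln 2 · 10
        expected = (10 - 5) * 10 / math.log(2)  # 72.134752...
        got = auc_lin_up_log_down(_prof([(0, 10), (10, 5)]), 0, 10)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(72.134752, abs=5e-7)

    def test_mixed_profile_with_flat_segment(self):
        prof = _prof([(0, 0), (10, 10), (20, 5), (30, 5)])
        expected = 50.0 + 5 * 10 / math.log(2) + 50.0  # flat part is linear
        assert auc_lin_up_log_down(prof, 0, 30) == pytest.approx(expected, rel=1e-12)

    def test_rejects_degenerate_windows(self):
        prof = _prof([(0, 1), (10, 2)])
        with pytest.raises(NcaError):
            auc_lin_up_log_down(prof, 10, 10)
        with pytest.raises(NcaError):
            auc_lin_up_log_down(_prof([(0, 1)]), 0, 10)
        with pytest.raises(NcaError, match="precedes"):
            auc_lin_up_log_down(prof, -5, 10)

    def test_exact_on_mono_exponential_decline(self):
        lam, c0 = 0.0143, 80.0
        t = np.array([0.0, 17.0, 41.0, 90.0, 160.0, 300.0])
        prof = ConcProfile("s", "plasma", t, c0 * np.exp(-lam * t))
        analytic = c0 / lam * (1 - math.exp(-lam * 300.0))
        assert auc_lin_up_log_down(prof, 0, 300) == pytest.approx(analytic, rel=1e-9)

    def test_additivity_at_arbitrary_split_points(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            prof = random_profile(rng)
            t0, t1 = prof.times[0], prof.times[-1]
            split = rng.uniform(t0, t1)
            whole = auc_lin_up_log_down(prof, t0, t1)
            parts = (auc_lin_up_log_down(prof, t0, split)
                     + auc_lin_up_log_down(prof, split, t1))
            assert parts == pytest.approx(whole, rel=1e-9, abs=1e-12)

    def test_matches_fine_grid_quadrature_on_random_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            prof = random_profile(rng)
            got = auc_lin_up_log_down(prof, prof.times[0], prof.times[-1])
            oracle = auc_fine_grid(prof)
            assert got == pytest.approx(oracle, rel=1e-6, abs=1e-9)


class TestCmaxTmax:
    def test_plasma_peak_at_first_midpoint(self):
        prof = _prof([(0, 0), (15, 53), (45, 30)])
        assert cmax_tmax(prof, (0, 480)) == (53.0, 15.0)

    def test_tie_broken_by_earliest_time(self):
        prof = _prof([(0, 0), (30, 10), (60, 10)])
        assert cmax_tmax(prof, (0, 480)) == (10.0, 30.0)

    def test_interval_two_uses_relative_clock(self):
        prof = _prof([(15, 3), (495, 7)])
        assert cmax_tmax(prof, (480, 960)) == (7.0, 15.0)

    def test_empty_interval_raises(self):
        with pytest.raises(NcaError):
            cmax_tmax(_prof([(15, 3)]), (480, 960))


class TestTerminalLambda:
    def test_exact_exponential_tail(self):
        prof = _prof([(0, 16), (30, 8), (60, 4), (90, 2)])
        est = terminal_lambda(prof, (0, 480))
        assert est.lambda_eq == pytest.approx(math.log(2) / 30, rel=1e-12)
        assert est.n_points == 3  # the Tmax point itself is excluded

    def test_near_flat_tail_follows_ols_sign(self):
        prof = _prof([(0, 16), (30, 10), (60, 9), (90, 10), (120, 9)])
        slope = ols_slope([30, 60, 90, 120], np.log([10, 9, 10, 9]))
        est = terminal_lambda(prof, (0, 480))
        assert slope < 0
        assert est.lambda_eq == pytest.approx(-slope, rel=1e-12)
        rising = _prof([(0, 16), (30, 9), (60, 10), (90, 9), (120, 10)])
        assert terminal_lambda(rising, (0, 480)).lambda_eq is None

    def test_insufficient_points_reports_reason(self):
        est = terminal_lambda(_prof([(0, 16), (30, 8), (60, 4)]), (0, 480))
        assert est.lambda_eq is None and est.reason == "insufficient points"
        assert est.n_points == 2


def test_half_life():
    assert half_life(math.log(2) / 46) == pytest.approx(46.0)
    assert half_life(0.00693147) == pytest.approx(100.0, rel=1e-5)
    assert half_life(None) is None
    assert half_life(-0.1) is None


def test_half_life_recovers_truth_through_lambda():
    lam = math.log(2) / 46.0
    t = np.array([0.0, 30, 60, 120, 240])
    prof = ConcProfile("s", "plasma", t, 50 * np.exp(-lam * t))
    est = terminal_lambda(prof, (0, 480))
    assert half_life(est.lambda_eq) == pytest.approx(46.0, rel=1e-9)


def test_penetration_ratio_matches_reported_table_values():
    assert penetration_ratio(4147, 2521) == pytest.approx(1.645, abs=5e-4)
    assert penetration_ratio(1886, 2521) == pytest.approx(0.748, abs=5e-4)
    assert penetration_ratio(7.0, 7.0) == 1.0
    with pytest.raises(NcaError):
        penetration_ratio(100.0, 0.0)


def test_compute_nca_produces_one_result_per_interval():
    lam = math.log(2) / 60.0
    t = np.concatenate([[0.0], np.arange(15, 480, 30.0), np.arange(495, 960, 30.0)])
    c = np.where(t < 480, 40 * np.exp(-lam * t), 40 * np.exp(-lam * (t - 480)))
    c[0] = 0.0
    prof = ConcProfile("s", "plasma", t, c, anchored=True)
    doses = [DoseEvent(0, 1500, 10), DoseEvent(480, 1500, 10)]
    res = compute_nca(prof, doses)
    assert [r.interval_index for r in res] == [1, 2]
    assert res[0].tmax == 15.0 and res[1].tmax == 15.0
    assert res[0].t_half == pytest.approx(60.0, rel=1e-6)
    # identical kinetics in both intervals -> near-identical metrics (the
    # interval-2 window starts at the carried-over washout level, not 0)
    assert res[1].auc == pytest.approx(res[0].auc, rel=1e-3)
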