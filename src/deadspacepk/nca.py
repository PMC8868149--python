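"""Non-compartmental PK metrics per subject × compartment × dosing interval.

AUC uses the linear-up/log-down trapezoidal rule: linear trapezoids on rising
(or zero-touching, or flat) segments, logarithmic trapezoids on positive
declining segments — the log rule is exact when the decline between two
samples is mono-exponential.  Cmax/Tmax are the observed maximum and the
earliest time attaining it; the terminal slope λ_eq is an ordinary
least-squares fit of ln(C) on t over all points strictly after Tmax within
the dosing interval, and T½ = ln 2 / λ_eq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import ConcProfile, dose_interval_windows, windowed_profile
from .study import DoseEvent


class NcaError(ValueError):
    pass


@dataclass(frozen=True)
class LambdaEstimate:
    lambda_eq: float | None  # 1/min; None when not estimable
    n_points: int
    reason: str | None = None  # set when lambda_eq is None


@dataclass
class NcaResult:
    subject_id: str
    compartment: str
    interval_index: int          # 1-based
    auc: float                   # min·µg/mL over the dosing-interval window
    cmax: float                  # µg/mL
    tmax: float                  # min from the interval's dose start
    lambda_eq: float | None      # 1/min
    t_half: float | None         # min
    n_lambda_points: int
    lambda_reason: str | None = None


def _segment_auc(t0: float, c0: float, t1: float, c1: float) -> float:
    dt = t1 - t0
    if c1 >= c0 or c0 <= 0 or c1 <= 0:
        return 0.5 * (c0 + c1) * dt
    # log trapezoid written via log1p so near-flat declines keep full precision
    r = (c0 - c1) / c1
    return c1 * r * dt / math.log1p(r)


def interp_conc(profile: ConcProfile, t: float) -> float:
    """Concentration at ``t`` under the AUC segment interpolant.

    Within a declining positive segment the interpolant is exponential,
    otherwise linear.  Beyond the last sample the final segment's rule is
    extended (log-decay continuation, or linear clipped at zero); before the
    first sample the profile does not cover ``t`` and an error is raised.
    """
    times, concs = profile.times, profile.concs
    if len(profile) < 2:
        raise NcaError("interpolation needs at least 2 points")
    if t < times[0]:
        raise NcaError(f"t={t} precedes the profile start {times[0]}")
    if t > times[-1]:
        t0, c0, t1, c1 = times[-2], concs[-2], times[-1], concs[-1]
        if c1 < c0 and c0 > 0 and c1 > 0:
            rate = math.log(c0 / c1) / (t1 - t0)
            return c1 * math.exp(-rate * (t - t1))
        slope = (c1 - c0) / (t1 - t0)
        return max(c1 + slope * (t - t1), 0.0)
    i = int(np.searchsorted(times, t, side="right") - 1)
    i = min(i, len(profile) - 2)
    t0, c0, t1, c1 = times[i], concs[i], times[i + 1], concs[i + 1]
    if t == t0:
        return float(c0)
    if c1 < c0 and c0 > 0 and c1 > 0:
        frac = (t - t0) / (t1 - t0)
        return float(c0 * (c1 / c0) ** frac)
    return float(c0 + (c1 - c0) * (t - t0) / (t1 - t0))


def _clipped_segment_auc(ta: float, ca: float, tb: float, cb: float,
                         lo: float, hi: float) -> float:
    """Area of one (possibly partially covered) sampled segment.

    The parent segment decides the rule; a window boundary falling inside it
    keeps that rule on both halves, which is what makes
    auc(t0,t1)+auc(t1,t2)=auc(t0,t2) hold exactly.
    """
    lo, hi = max(lo, ta), min(hi, tb)
    if hi <= lo:
        return 0.0
    if cb < ca and ca > 0 and cb > 0:  # log-down parent
        rate = math.log(ca / cb) / (tb - ta)
        c_lo = ca * math.exp(-rate * (lo - ta))
        c_hi = ca * math.exp(-rate * (hi - ta))
        r = (c_lo - c_hi) / c_hi
        return c_hi * r * (hi - lo) / math.log1p(r)
    slope = (cb - ca) / (tb - ta)
    c_lo = ca + slope * (lo - ta)
    c_hi = ca + slope * (hi - ta)
    return 0.5 * (c_lo + c_hi) * (hi - lo)


def auc_lin_up_log_down(profile: ConcProfile, t0: float, t1: float) -> float:
    """Linear-up/log-down trapezoidal AUC over the window [t0, t1]."""
    if len(profile) < 2:
        raise NcaError("AUC needs at least 2 points")
    if t1 <= t0:
        raise NcaError(f"AUC window end {t1} must exceed start {t0}")
    times, concs = profile.times, profile.concs
    if t0 < times[0]:
        raise NcaError(f"window start {t0} precedes profile start {times[0]}")
    total = 0.0
    for i in range(len(profile) - 1):
        total += _clipped_segment_auc(times[i], concs[i], times[i + 1], concs[i + 1],
                                      t0, t1)
    if t1 > times[-1]:
        # extend the final segment's rule across the uncovered tail
        lo = max(t0, float(times[-1]))
        total += _segment_auc(lo, interp_conc(profile, lo), t1, interp_conc(profile, t1))
    return float(total)


def cmax_tmax(profile: ConcProfile, interval: tuple[float, float]) -> tuple[float, float]:
    """Observed maximum and earliest time attaining it, on the interval's clock.

    ``interval`` is the half-open [dose_start, next_dose_start) window; Tmax
    is reported in minutes after the interval's dose start.
    """
    start, end = interval
    mask = (profile.times >= start) & (profile.times < end)
    if not np.any(mask):
        raise NcaError(f"no points in interval [{start}, {end})")
    t, c = profile.times[mask], profile.concs[mask]
    i = int(np.argmax(c))  # argmax returns the first (earliest) maximum
    return float(c[i]), float(t[i] - start)


def terminal_lambda(profile: ConcProfile, interval: tuple[float, float],
                    min_points: int = 3) -> LambdaEstimate:
    """Terminal elimination rate λ_eq from log-linear OLS after Tmax.

    Uses all strictly-post-Tmax points with positive concentration inside the
    interval.  Not estimable (``lambda_eq=None``) with fewer than
    ``min_points`` such points or a non-negative fitted slope.
    """
    start, end = interval
    _, tmax_rel = cmax_tmax(profile, interval)
    tmax_abs = start + tmax_rel
    mask = (profile.times > tmax_abs) & (profile.times >= start) \
        & (profile.times < end) & (profile.concs > 0)
    n = int(mask.sum())
    if n < min_points:
        return LambdaEstimate(None, n, "insufficient points")
    slope = np.polyfit(profile.times[mask], np.log(profile.concs[mask]), 1)[0]
    if slope >= 0:
        return LambdaEstimate(None, n, "non-negative slope")
    return LambdaEstimate(float(-slope), n)


def half_life(lambda_eq: float | None) -> float | None:
    """T½ = ln 2 / λ_eq; undefined when λ_eq is undefined or non-positive."""
    if lambda_eq is None or lambda_eq <= 0:
        return None
    return math.log(2.0) / lambda_eq


def penetration_ratio(auc_tissue: float, auc_plasma: float) -> float:
    """Tissue exposure index AUC_tissue / AUC_plasma."""
    if auc_plasma <= 0:
        raise NcaError(f"plasma AUC must be > 0, got {auc_plasma}")
    return auc_tissue / auc_plasma


def compute_nca(profile: ConcProfile, doses: Sequence[DoseEvent],
                study_end: float = 960.0, min_lambda_points: int = 3) -> list[NcaResult]:
    """All NCA metrics for one profile, one result per dosing interval."""
    windows = dose_interval_windows(doses, study_end)
    out: list[NcaResult] = []
    for k, (start, end) in enumerate(windows, start=1):
        # dose times are slope discontinuities: AUC integrates the window's own
        # points, with boundary values carried by the preceding washout segment
        auc = auc_lin_up_log_down(windowed_profile(profile, start, end, "auc"),
                                  start, end)
        cmax, tmax = cmax_tmax(profile, (start, end))
        lam = terminal_lambda(profile, (start, end), min_points=min_lambda_points)
        out.append(NcaResult(profile.subject_id, profile.compartment, k, auc,
                             cmax, tmax, lam.lambda_eq, half_life(lam.lambda_eq),
                             lam.n_points, lam.reason))
    return out


def nca_frame(results: Sequence[NcaResult]) -> pd.DataFrame:
    rows = [(r.subject_id, r.compartment, r.interval_index, r.auc, r.cmax, r.tmax,
             r.lambda_eq, r.t_half, r.n_lambda_points) for r in results]
    return pd.DataFrame(rows, columns=["subject_id", "compartment", "interval", "auc",
                                       "cmax", "tmax", "lambda", "t_half",
                                       "n_lambda_points"])
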