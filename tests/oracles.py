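"""Independent numeric oracles for the AUC and time-above-MIC rules.

These evaluate the piecewise interpolant (linear on rising or zero-touching
segments, exponential on positive declines) on fine grids and integrate or
measure it numerically — no code shared with the implementation under test.
"""

import numpy as np


def _segment_values(t0, c0, t1, c1, ts):
    frac = (ts - t0) / (t1 - t0)
    if c1 < c0 and c0 > 0 and c1 > 0:
        return c0 * (c1 / c0) ** frac
    return c0 + (c1 - c0) * frac


def auc_fine_grid(profile, n_per_segment: int = 4001) -> float:
    """Trapezoid quadrature of the segment interpolant over the full span."""
    total = 0.0
    t, c = profile.times, profile.concs
    for i in range(len(t) - 1):
        ts = np.linspace(t[i], t[i + 1], n_per_segment)
        total += np.trapezoid(_segment_values(t[i], c[i], t[i + 1], c[i + 1], ts), ts)
    return total


def time_above_fine_grid(profile, mic: float, dt: float = 1e-4) -> float:
    """Midpoint-counting measure of {t: C(t) > mic} for the LINEAR interpolant."""
    t0, t1 = profile.times[0], profile.times[-1]
    n = int(np.ceil((t1 - t0) / dt))
    ts = t0 + (np.arange(n) + 0.5) * ((t1 - t0) / n)
    vals = np.interp(ts, profile.times, profile.concs)
    return float(np.count_nonzero(vals > mic) * ((t1 - t0) / n))


def ols_slope(x, y) -> float:
    """Closed-form simple-regression slope."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())
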