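"""Recovery-corrected, time-ordered concentration–time profiles.

Dialysate measurements are interval averages; after recovery correction they
are placed at the midpoint of their collection interval, which time-aligns
them with the mid-interval plasma reference draws.  Profiles for drug-naïve
subjects are anchored at (0, 0).  The profile keeps an absolute clock across
both dosing intervals; the second interval is never re-anchored, so the last
first-interval concentration carries across the 480-min dose by
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .study import DialysateRecord, DoseEvent, PlasmaRecord, SamplingInterval
from .calibration import RecoveryEstimate, correct_concentration


class ProfileError(ValueError):
    pass


@dataclass
class ConcProfile:
    subject_id: str
    compartment: str  # plasma | deadspace | bone
    times: np.ndarray  # min, strictly increasing
    concs: np.ndarray  # µg/mL, >= 0
    anchored: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.times.shape != self.concs.shape or self.times.ndim != 1:
            raise ProfileError("times and concs must be matching 1-D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ProfileError("profile times must be strictly increasing")
        if np.any(self.concs < 0):
            raise ProfileError("profile concentrations must be non-negative")
        if self.anchored and self.times.size and (self.times[0] != 0 or self.concs[0] != 0):
            raise ProfileError("anchored profile must start at (0, 0)")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.concs.tolist()))


def midpoint_time(interval: SamplingInterval) -> float:
    """Representative time of an interval-averaged measurement."""
    return interval.midpoint


def apply_blq_rule(records: Sequence[DialysateRecord]) -> list[DialysateRecord]:
    """Resolve below-LOQ dialysate drug values before profile building.

    Records flagged below the drug LOQ are set to 0 when they fall after the
    last quantifiable record (true washout) and dropped (treated as missing)
    when they occur earlier.  Time order is by interval start.
    """
    ordered = sorted(records, key=lambda r: r.interval.t_start)
    last_quant = max((i for i, r in enumerate(ordered) if not r.blq_flag), default=-1)
    out: list[DialysateRecord] = []
    for i, r in enumerate(ordered):
        if not r.blq_flag:
            out.append(r)
        elif i > last_quant:
            out.append(DialysateRecord(r.subject_id, r.compartment, r.interval,
                                       0.0, r.calibrator_conc, blq_flag=True))
        # earlier BLQ: missing, dropped
    return out


def build_profile(records: Sequence[DialysateRecord] | Sequence[PlasmaRecord],
                  recovery: RecoveryEstimate | None = None,
                  anchor_at_zero: bool = False) -> ConcProfile:
    """Turn raw records of one subject × compartment into a ConcProfile.

    Dialysate records require a recovery estimate and are corrected and
    midpoint-placed; plasma records are used verbatim at their recorded
    times.
    """
    if not records:
        raise ProfileError("cannot build a profile from zero records")
    first = records[0]
    if isinstance(first, DialysateRecord):
        if recovery is None:
            raise ProfileError(
                f"recovery estimate required for dialysate compartment {first.compartment!r}")
        subject_id, compartment = first.subject_id, first.compartment
        pts = [(midpoint_time(r.interval),
                correct_concentration(r.drug_conc, recovery.recovery_pct))
               for r in records]
    else:
        subject_id, compartment = first.subject_id, "plasma"
        pts = [(r.time, r.free_conc) for r in records]
    pts.sort(key=lambda p: p[0])
    times = [p[0] for p in pts]
    if len(set(times)) != len(times):
        raise ProfileError(f"duplicate sample times in {subject_id}/{compartment}")
    if anchor_at_zero:
        if times and times[0] == 0:
            raise ProfileError("cannot anchor: a sample already sits at t=0")
        pts.insert(0, (0.0, 0.0))
    return ConcProfile(subject_id, compartment,
                       np.array([p[0] for p in pts]), np.array([p[1] for p in pts]),
                       anchored=anchor_at_zero)


def dose_interval_windows(doses: Sequence[DoseEvent],
                          study_end: float = 960.0) -> list[tuple[float, float]]:
    """Half-open [start, end) analysis windows, one per dose."""
    starts = [d.start_time for d in doses]
    if starts != sorted(starts):
        raise ProfileError("doses must be sorted by start_time")
    ends = starts[1:] + [study_end]
    return list(zip(starts, ends))


def split_by_dose_interval(profile: ConcProfile, doses: Sequence[DoseEvent],
                           study_end: float = 960.0) -> list[ConcProfile]:
    """Partition profile points into dosing intervals (absolute clock kept).

    The (0, 0) anchor counts in interval 1.  A non-anchor point before the
    first dose is an error.
    """
    windows = dose_interval_windows(doses, study_end)
    t0 = windows[0][0]
    bad = profile.times < t0
    if profile.anchored:
        bad[0] = False
    if np.any(bad):
        raise ProfileError(
            f"profile point at t={profile.times[bad][0]} precedes the first dose at {t0}")
    parts: list[ConcProfile] = []
    for k, (start, end) in enumerate(windows):
        mask = (profile.times >= start) & (profile.times < end)
        if k == 0 and profile.anchored:
            mask[0] = True
        parts.append(ConcProfile(profile.subject_id, profile.compartment,
                                 profile.times[mask], profile.concs[mask],
                                 anchored=profile.anchored and k == 0))
    return parts


def _extrapolate(t: float, t0: float, c0: float, t1: float, c1: float,
                 rule: str) -> float:
    """Extend the segment (t0,c0)-(t1,c1) to time t (t > t1).

    ``rule='auc'`` continues a positive decline exponentially (matching the
    log-down AUC interpolant) and anything else linearly, clipped at zero;
    ``rule='linear'`` always continues linearly, clipped at zero.
    """
    if rule == "auc" and c1 < c0 and c0 > 0 and c1 > 0:
        rate = np.log(c0 / c1) / (t1 - t0)
        return float(c1 * np.exp(-rate * (t - t1)))
    slope = (c1 - c0) / (t1 - t0)
    return max(float(c1 + slope * (t - t1)), 0.0)


def windowed_profile(profile: ConcProfile, start: float, end: float,
                     rule: str = "auc") -> ConcProfile:
    """Restrict a profile to one dosing-interval window [start, end].

    Dose times are treated as segment breakpoints: no interpolation segment
    may span them, because the infusion makes the true curve discontinuous in
    slope there.  Boundary concentrations without an exact sample are carried
    by extrapolating the *preceding within-window* (or pre-window, for the
    start) segment under ``rule`` — the washout carries across a dose, the
    post-dose rise does not bleed backwards.
    """
    if end <= start:
        raise ProfileError(f"window end {end} must exceed start {start}")
    t, c = profile.times, profile.concs
    inside = (t > start) & (t < end)
    pts = list(zip(t[inside].tolist(), c[inside].tolist()))

    if np.any(t == start):
        c_start = float(c[t == start][0])
    else:
        before = np.flatnonzero(t < start)
        if before.size >= 2:
            i, j = before[-2], before[-1]
            c_start = _extrapolate(start, t[i], c[i], t[j], c[j], rule)
        elif before.size == 1:
            c_start = float(c[before[-1]])
        else:
            raise ProfileError(f"profile does not cover window start {start}")
    pts.insert(0, (start, c_start))

    if np.any(t == end):
        c_end = float(c[t == end][0])
    else:
        if len(pts) >= 2:
            (t0, c0), (t1, c1) = pts[-2], pts[-1]
            c_end = _extrapolate(end, t0, c0, t1, c1, rule)
        else:
            c_end = pts[-1][1]
    pts.append((end, c_end))
    return ConcProfile(profile.subject_id, profile.compartment,
                       np.array([p[0] for p in pts]), np.array([p[1] for p in pts]),
                       anchored=profile.anchored and start == 0)


def profiles_frame(profiles: Sequence[ConcProfile]):
    """Flatten profiles to the tidy profiles.csv layout."""
    import pandas as pd

    rows = [(p.subject_id, p.compartment, t, c)
            for p in profiles for t, c in zip(p.times, p.concs)]
    return pd.DataFrame(rows, columns=["subject_id", "compartment", "time_min", "conc_ug_ml"])
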