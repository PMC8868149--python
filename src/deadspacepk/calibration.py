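"""Internal-standard (retrodialysis-by-loss) recovery calibration.

Each catheter is perfused with saline carrying a known calibrator
concentration; the fraction of calibrator lost across the membrane estimates
the relative recovery of the catheter, RR% = 100·(1 − C_dialysate/C_perfusate).
Dialysate drug concentrations are divided by the recovery fraction to obtain
absolute free tissue concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Sequence

from .study import CALIBRATOR_LOQ, CatheterSpec, DialysateRecord


class CalibrationError(ValueError):
    """Calibrator measurement inconsistent with a working catheter."""


class RecoveryNotDeterminable(ValueError):
    """No usable calibrator measurements; the catheter needs imputation."""


@dataclass(frozen=True)
class RecoveryEstimate:
    subject_id: str
    compartment: str
    recovery_pct: float
    n_intervals_used: int
    provenance: str  # "measured" | "imputed"


def relative_recovery(c_dial_cal: float, c_perf: float) -> float:
    """Per-interval relative recovery (%) from calibrator loss.

    ``c_dial_cal`` is the calibrator concentration remaining in the dialysate;
    ``c_perf`` the concentration entering with the perfusate.
    """
    if c_perf <= 0:
        raise CalibrationError(f"perfusate calibrator concentration must be > 0, got {c_perf}")
    if c_dial_cal < 0:
        raise CalibrationError(f"calibrator concentration must be >= 0, got {c_dial_cal}")
    if c_dial_cal > c_perf:
        raise CalibrationError(
            f"dialysate calibrator {c_dial_cal} exceeds perfusate {c_perf}: "
            "negative recovery signals catheter failure")
    return 100.0 * (1.0 - c_dial_cal / c_perf)


def catheter_recovery(records: Sequence[DialysateRecord], spec: CatheterSpec,
                      calibrator_loq: float = CALIBRATOR_LOQ) -> RecoveryEstimate:
    """One time-constant recovery per catheter: the mean of the per-interval values.

    Calibrator measurements below the calibrator LOQ are excluded; if none
    remain, raises :class:`RecoveryNotDeterminable` so the caller can impute
    from the rest of the cohort.
    """
    usable = [r for r in records if r.calibrator_conc >= calibrator_loq]
    if not usable:
        raise RecoveryNotDeterminable(
            f"subject {spec.subject_id} {spec.compartment}: no calibrator "
            f"measurement at or above LOQ {calibrator_loq} µg/mL")
    # assay noise can push an individual measurement above c_perf (a negative
    # per-interval recovery); those average out — only a non-positive MEAN
    # marks the catheter as failed
    values = [100.0 * (1.0 - r.calibrator_conc / spec.perfusate_calibrator_ug_ml)
              for r in usable]
    pct = fmean(values)
    if pct <= 0:
        raise CalibrationError(
            f"subject {spec.subject_id} {spec.compartment}: mean recovery "
            f"{pct:.2f}% is not positive — catheter failure")
    return RecoveryEstimate(spec.subject_id, spec.compartment, pct, len(values), "measured")


def impute_missing_recovery(cohort_estimates: Iterable[RecoveryEstimate],
                            target: CatheterSpec) -> RecoveryEstimate:
    """Fill an undeterminable catheter with the cohort mean of its compartment.

    Only measured estimates from the same compartment type contribute.
    """
    peers = [e.recovery_pct for e in cohort_estimates
             if e.compartment == target.compartment and e.provenance == "measured"
             and not (e.subject_id == target.subject_id)]
    if not peers:
        raise RecoveryNotDeterminable(
            f"no measured {target.compartment} recovery anywhere in the cohort "
            f"to impute subject {target.subject_id}")
    return RecoveryEstimate(target.subject_id, target.compartment,
                            fmean(peers), 0, "imputed")


def correct_concentration(c_dial: float, recovery_pct: float) -> float:
    """Absolute tissue concentration from a dialysate measurement.

    C_tissue = C_dialysate / (RR/100); with partial recovery the corrected
    value is always at least the measured one.
    """
    if recovery_pct <= 0:
        raise CalibrationError(f"recovery must be > 0 to correct, got {recovery_pct}")
    if recovery_pct > 100:
        raise CalibrationError(f"recovery cannot exceed 100%, got {recovery_pct}")
    if c_dial < 0:
        raise CalibrationError(f"concentration must be >= 0, got {c_dial}")
    return c_dial / (recovery_pct / 100.0)
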