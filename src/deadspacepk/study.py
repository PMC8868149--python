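"""Domain types, CSV I/O and validation for a multi-subject microdialysis study.

A study bundles, per subject: intravenous dose events, microdialysis catheter
specifications, interval-averaged dialysate measurements (drug + internal
calibrator) from the tissue compartments, and mid-interval free plasma
reference samples.  All times are minutes from the start of the first
infusion; collection intervals are half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

#: Lower limit of quantification of the drug assay (µg/mL).
DRUG_LOQ = 0.01
#: Lower limit of quantification of the internal-calibrator assay (µg/mL).
CALIBRATOR_LOQ = 0.05
#: Epidemiological cut-off MIC for S. aureus used as the default PD threshold (µg/mL).
DEFAULT_MIC = 4.0

#: Tissue compartments sampled by microdialysis.
DIALYSATE_COMPARTMENTS = ("deadspace", "bone")
#: All compartments, in canonical reporting order.
COMPARTMENTS = ("plasma", "deadspace", "bone")


class SchemaError(ValueError):
    """An input table is missing a required column or contains no records."""


class ReferenceError_(ValueError):
    """A record refers to a subject/catheter that does not exist."""


@dataclass(frozen=True)
class DoseEvent:
    start_time: float  # min from study start
    dose_mg: float
    infusion_min: float

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError(f"dose start_time must be >= 0, got {self.start_time}")
        if self.dose_mg <= 0:
            raise ValueError(f"dose_mg must be > 0, got {self.dose_mg}")
        if self.infusion_min < 0:
            raise ValueError(f"infusion_min must be >= 0, got {self.infusion_min}")


@dataclass(frozen=True)
class SamplingInterval:
    # t_end > t_start is a content invariant checked by validate_study, not here,
    # so malformed input rows remain representable and reportable.
    t_start: float
    t_end: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class DialysateRecord:
    subject_id: str
    compartment: str
    interval: SamplingInterval
    drug_conc: float        # µg/mL, as measured in the dialysate
    calibrator_conc: float  # µg/mL, internal calibrator remaining in the dialysate
    blq_flag: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in DIALYSATE_COMPARTMENTS:
            raise ValueError(f"unknown dialysate compartment {self.compartment!r}")


@dataclass(frozen=True)
class PlasmaRecord:
    subject_id: str
    time: float       # min; midpoint of the matching collection interval
    free_conc: float  # µg/mL free (unbound) drug


@dataclass(frozen=True)
class CatheterSpec:
    subject_id: str
    compartment: str
    membrane_mm: float
    flow_ul_min: float = 2.0
    perfusate_calibrator_ug_ml: float = 5.0

    def __post_init__(self) -> None:
        if self.perfusate_calibrator_ug_ml <= 0:
            raise ValueError("perfusate calibrator concentration must be > 0")
        if self.flow_ul_min <= 0:
            raise ValueError("flow rate must be > 0")


@dataclass
class Subject:
    subject_id: str
    doses: list[DoseEvent]
    catheters: list[CatheterSpec]
    dialysates: list[DialysateRecord]
    plasma: list[PlasmaRecord]
    weight_kg: float | None = None
    weight_group: str | None = None

    def catheter(self, compartment: str) -> CatheterSpec:
        for spec in self.catheters:
            if spec.compartment == compartment:
                return spec
        raise ReferenceError_(
            f"subject {self.subject_id}: no catheter for compartment {compartment!r}"
        )

    def dialysates_for(self, compartment: str) -> list[DialysateRecord]:
        return [r for r in self.dialysates if r.compartment == compartment]


@dataclass
class CohortStudy:
    subjects: list[Subject] = field(default_factory=list)
    mic: float = DEFAULT_MIC

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


@dataclass(frozen=True)
class Violation:
    subject_id: str | None
    where: str
    message: str


# --------------------------------------------------------------------------
# Schedule helpers

def standard_sampling_intervals(interval_start: float) -> list[SamplingInterval]:
    """Collection schedule within one 8-h dosing interval.

    Eight 30-min collections over the first 4 h, then four 60-min collections
    over the second 4 h — 12 intervals per dosing interval.
    """
    out = [SamplingInterval(interval_start + 30 * k, interval_start + 30 * (k + 1))
           for k in range(8)]
    out += [SamplingInterval(interval_start + 240 + 60 * k,
                             interval_start + 240 + 60 * (k + 1)) for k in range(4)]
    return out


def standard_schedule(dose_times: Sequence[float] = (0.0, 480.0)) -> list[SamplingInterval]:
    """Full collection schedule across all dosing intervals (24 for two doses)."""
    out: list[SamplingInterval] = []
    for t0 in dose_times:
        out.extend(standard_sampling_intervals(t0))
    return out


def assign_weight_group(weight_kg: float) -> str:
    """Label a subject by the nearest of the study's three weight bands."""
    centers = {"53-57 kg": 55.0, "73-77 kg": 75.0, "93-97 kg": 95.0}
    return min(centers, key=lambda g: abs(centers[g] - weight_kg))


# --------------------------------------------------------------------------
# CSV I/O

DOSE_COLUMNS = ["subject_id", "start_time_min", "dose_mg", "infusion_min"]
DIALYSATE_COLUMNS = ["subject_id", "compartment", "t_start_min", "t_end_min",
                     "drug_conc_ug_ml", "calibrator_conc_ug_ml"]
PLASMA_COLUMNS = ["subject_id", "time_min", "free_conc_ug_ml"]
CATHETER_COLUMNS = ["subject_id", "compartment", "membrane_mm", "flow_ul_min",
                    "perfusate_calibrator_ug_ml"]
SUBJECT_COLUMNS = ["subject_id", "weight_kg"]


def _read_checked(path: str | os.PathLike, required: Sequence[str],
                  allow_empty: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0 and not allow_empty:
        raise SchemaError(f"{path}: contains zero records")
    return df


def load_study(dose_csv, dialysate_csv, plasma_csv, catheter_csv,
               subjects_csv=None, mic: float = DEFAULT_MIC,
               drug_loq: float = DRUG_LOQ) -> CohortStudy:
    """Read the four (optionally five) study tables into a cross-referenced cohort.

    Raises :class:`SchemaError` for missing columns or empty measurement
    tables, and :class:`ReferenceError_` for dialysate records with no
    matching catheter.  Drug concentrations below ``drug_loq`` are flagged,
    never altered.
    """
    doses = _read_checked(dose_csv, DOSE_COLUMNS)
    dials = _read_checked(dialysate_csv, DIALYSATE_COLUMNS)
    plasma = _read_checked(plasma_csv, PLASMA_COLUMNS)
    caths = _read_checked(catheter_csv, CATHETER_COLUMNS)
    weights: dict[str, float] = {}
    if subjects_csv is not None:
        subj = _read_checked(subjects_csv, SUBJECT_COLUMNS, allow_empty=True)
        weights = dict(zip(subj["subject_id"], subj["weight_kg"].astype(float)))

    subject_ids = list(dict.fromkeys(doses["subject_id"]))
    cath_index: dict[tuple[str, str], CatheterSpec] = {}
    for row in caths.itertuples(index=False):
        spec = CatheterSpec(row.subject_id, row.compartment, float(row.membrane_mm),
                            float(row.flow_ul_min), float(row.perfusate_calibrator_ug_ml))
        cath_index[(row.subject_id, row.compartment)] = spec

    subjects: dict[str, Subject] = {}
    for sid in subject_ids:
        w = weights.get(sid)
        subjects[sid] = Subject(
            subject_id=sid, doses=[], catheters=[], dialysates=[], plasma=[],
            weight_kg=w, weight_group=assign_weight_group(w) if w is not None else None)

    for row in doses.itertuples(index=False):
        subjects[row.subject_id].doses.append(
            DoseEvent(float(row.start_time_min), float(row.dose_mg), float(row.infusion_min)))
    for s in subjects.values():
        s.doses.sort(key=lambda d: d.start_time)
        s.catheters = [spec for (sid, _), spec in cath_index.items() if sid == s.subject_id]

    for row in dials.itertuples(index=False):
        if (row.subject_id, row.compartment) not in cath_index:
            raise ReferenceError_(
                f"dialysate record for subject {row.subject_id!r} compartment "
                f"{row.compartment!r} has no matching catheter")
        if row.subject_id not in subjects:
            raise ReferenceError_(f"dialysate record for unknown subject {row.subject_id!r}")
        drug = float(row.drug_conc_ug_ml)
        subjects[row.subject_id].dialysates.append(DialysateRecord(
            row.subject_id, row.compartment,
            SamplingInterval(float(row.t_start_min), float(row.t_end_min)),
            drug, float(row.calibrator_conc_ug_ml), blq_flag=drug < drug_loq))

    for row in plasma.itertuples(index=False):
        if row.subject_id not in subjects:
            raise ReferenceError_(f"plasma record for unknown subject {row.subject_id!r}")
        subjects[row.subject_id].plasma.append(
            PlasmaRecord(row.subject_id, float(row.time_min), float(row.free_conc_ug_ml)))

    for s in subjects.values():
        s.dialysates.sort(key=lambda r: (r.compartment, r.interval.t_start))
        s.plasma.sort(key=lambda r: r.time)
    return CohortStudy(subjects=list(subjects.values()), mic=mic)


def study_frames(study: CohortStudy) -> dict[str, pd.DataFrame]:
    """Flatten a cohort back into the five canonical tables."""
    dose_rows, dial_rows, plasma_rows, cath_rows, subj_rows = [], [], [], [], []
    for s in study.subjects:
        for d in s.doses:
            dose_rows.append((s.subject_id, d.start_time, d.dose_mg, d.infusion_min))
        for r in sorted(s.dialysates, key=lambda r: (r.compartment, r.interval.t_start)):
            dial_rows.append((s.subject_id, r.compartment, r.interval.t_start,
                              r.interval.t_end, r.drug_conc, r.calibrator_conc))
        for r in s.plasma:
            plasma_rows.append((s.subject_id, r.time, r.free_conc))
        for c in s.catheters:
            cath_rows.append((s.subject_id, c.compartment, c.membrane_mm,
                              c.flow_ul_min, c.perfusate_calibrator_ug_ml))
        if s.weight_kg is not None:
            subj_rows.append((s.subject_id, s.weight_kg))
    frames = {
        "doses": pd.DataFrame(dose_rows, columns=DOSE_COLUMNS),
        "dialysates": pd.DataFrame(dial_rows, columns=DIALYSATE_COLUMNS),
        "plasma": pd.DataFrame(plasma_rows, columns=PLASMA_COLUMNS),
        "catheters": pd.DataFrame(cath_rows, columns=CATHETER_COLUMNS),
    }
    if subj_rows:
        frames["subjects"] = pd.DataFrame(subj_rows, columns=SUBJECT_COLUMNS)
    return frames


def write_study(study: CohortStudy, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the cohort as the canonical CSVs; returns {table: path}."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = {}
    for name, df in study_frames(study).items():
        path = os.path.join(str(out_dir), f"{name}.csv")
        df.to_csv(path, index=False)
        manifest[name] = path
    return manifest


def write_results(results: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike) -> dict[str, str]:
    """Write result tables as CSVs with deterministic column order.

    ``results`` maps table name -> DataFrame; empty frames produce
    headers-only files.  Returns {table: path}.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = {}
    for name in results:
        path = os.path.join(str(out_dir), f"{name}.csv")
        results[name].to_csv(path, index=False)
        manifest[name] = path
    return manifest


# --------------------------------------------------------------------------
# Validation

def validate_study(study: CohortStudy) -> list[Violation]:
    """Collect invariant violations without raising on content problems."""
    out: list[Violation] = []
    if study.mic <= 0:
        out.append(Violation(None, "study", f"mic must be > 0, got {study.mic}"))
    for s in study.subjects:
        if not s.doses:
            out.append(Violation(s.subject_id, "doses", "no dose events"))
        compartments_with_catheter = {c.compartment for c in s.catheters}
        for i, r in enumerate(s.dialysates):
            where = f"dialysate[{i}] {r.compartment} [{r.interval.t_start},{r.interval.t_end})"
            if r.interval.t_end <= r.interval.t_start:
                out.append(Violation(s.subject_id, where, "t_end <= t_start"))
            if r.drug_conc < 0:
                out.append(Violation(s.subject_id, where, f"negative drug conc {r.drug_conc}"))
            if r.calibrator_conc < 0:
                out.append(Violation(s.subject_id, where,
                                     f"negative calibrator conc {r.calibrator_conc}"))
            if r.compartment not in compartments_with_catheter:
                out.append(Violation(s.subject_id, where, "no catheter for compartment"))
        for i, r in enumerate(s.plasma):
            if r.time < 0:
                out.append(Violation(s.subject_id, f"plasma[{i}]", f"negative time {r.time}"))
            if r.free_conc < 0:
                out.append(Violation(s.subject_id, f"plasma[{i}]",
                                     f"negative concentration {r.free_conc}"))
    return out
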