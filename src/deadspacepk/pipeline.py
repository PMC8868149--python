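"""End-to-end orchestration: simulate or load a study, calibrate recoveries,
build profiles, compute NCA and PD metrics, summarize, write outputs."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .calibration import (CalibrationError, RecoveryEstimate,
                          RecoveryNotDeterminable, catheter_recovery,
                          impute_missing_recovery)
from .nca import compute_nca, nca_frame
from .pdmetrics import compute_pd, pd_frame
from .profiles import apply_blq_rule, build_profile, profiles_frame
from .simulate import default_params_calibrated, ground_truth_frame, simulate_cohort
from .study import (CohortStudy, DIALYSATE_COMPARTMENTS, load_study, validate_study,
                    write_results, write_study)
from .summary import summarize_cohort

log = logging.getLogger("deadspacepk")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "simulate"           # simulate | analyze
    out_dir: str = "out"
    seed: int = 0
    mic: float = 4.0
    confidence_level: float = 0.95
    lambda_min_points: int = 3
    study_end: float = 960.0
    # simulate mode
    n_per_group: int = 6
    weight_groups: tuple = (55.0, 75.0, 95.0)
    noise_cv: float | None = None    # None -> simulator default
    # analyze mode: paths to the study CSVs
    inputs: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError(f"mode must be simulate or analyze, got {self.mode!r}")
        if self.mic <= 0:
            raise ConfigError(f"mic must be > 0, got {self.mic}")
        if not 0 < self.confidence_level < 1:
            raise ConfigError("confidence_level must be in (0, 1)")
        if self.lambda_min_points < 2:
            raise ConfigError("lambda_min_points must be >= 2")
        if self.mode == "analyze":
            required = {"doses", "dialysates", "plasma", "catheters"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(f"analyze mode needs input paths: {sorted(missing)}")


def config_from_yaml(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    if isinstance(cfg.weight_groups, list):
        cfg.weight_groups = tuple(cfg.weight_groups)
    return cfg


def calibrate_recoveries(study: CohortStudy) -> tuple[list[RecoveryEstimate], list[str]]:
    """Per-catheter recovery, with cohort-mean imputation for failures."""
    measured: list[RecoveryEstimate] = []
    pending = []
    warnings: list[str] = []
    for s in study.subjects:
        for comp in DIALYSATE_COMPARTMENTS:
            recs = s.dialysates_for(comp)
            if not recs:
                continue
            spec = s.catheter(comp)
            try:
                measured.append(catheter_recovery(recs, spec))
            except (RecoveryNotDeterminable, CalibrationError):
                pending.append(spec)  # failed/undeterminable -> cohort-mean imputation
    estimates = list(measured)
    for spec in pending:
        est = impute_missing_recovery(measured, spec)
        warnings.append(f"recovery imputed for {spec.subject_id}/{spec.compartment}: "
                        f"{est.recovery_pct:.1f}% (cohort mean)")
        estimates.append(est)
    return estimates, warnings


def recoveries_frame(estimates: Sequence[RecoveryEstimate]) -> pd.DataFrame:
    rows = [(e.subject_id, e.compartment, e.recovery_pct, e.n_intervals_used, e.provenance)
            for e in estimates]
    return pd.DataFrame(rows, columns=["subject_id", "compartment", "recovery_pct",
                                       "n_intervals_used", "provenance"])


def analyze_study(study: CohortStudy, mic: float | None = None,
                  confidence_level: float = 0.95, lambda_min_points: int = 3,
                  study_end: float = 960.0) -> dict:
    """Run calibration → profiles → NCA → PD → cohort summary on a cohort."""
    mic = study.mic if mic is None else mic
    violations = validate_study(study)
    if violations:
        details = "; ".join(f"{v.subject_id}/{v.where}: {v.message}" for v in violations[:5])
        raise ValueError(f"study fails validation ({len(violations)} problems): {details}")

    estimates, warnings = calibrate_recoveries(study)
    est_index = {(e.subject_id, e.compartment): e for e in estimates}

    all_profiles, nca_results, pd_results = [], [], []
    for s in study.subjects:
        profs = []
        if s.plasma:
            profs.append(build_profile(s.plasma, anchor_at_zero=True))
        for comp in DIALYSATE_COMPARTMENTS:
            recs = apply_blq_rule(s.dialysates_for(comp))
            if not recs:
                continue
            profs.append(build_profile(recs, est_index[(s.subject_id, comp)],
                                       anchor_at_zero=True))
        for prof in profs:
            nca_results.extend(compute_nca(prof, s.doses, study_end, lambda_min_points))
            pd_results.extend(compute_pd(prof, s.doses, mic, study_end))
        all_profiles.extend(profs)

    nca_df, pd_df = nca_frame(nca_results), pd_frame(pd_results)
    for r in nca_results:
        if r.lambda_eq is None:
            warnings.append(f"lambda undefined for {r.subject_id}/{r.compartment} "
                            f"interval {r.interval_index}: {r.lambda_reason}")
    for r in pd_results:
        if r.time_to_threshold is None:
            warnings.append(f"threshold {mic} µg/mL never reached for "
                            f"{r.subject_id}/{r.compartment} interval {r.interval_index}")

    weights = None
    if any(s.weight_kg is not None for s in study.subjects):
        weights = pd.DataFrame(
            [(s.subject_id, s.weight_kg, s.weight_group) for s in study.subjects],
            columns=["subject_id", "weight_kg", "weight_group"])
    tables = summarize_cohort(nca_df, pd_df, weights, confidence_level)
    warnings.extend(tables["metadata"]["warnings"])
    tables["metadata"]["warnings"] = warnings
    return {"recoveries": estimates, "profiles": all_profiles,
            "nca": nca_df, "pd": pd_df, "tables": tables, "warnings": warnings}


def run(config: RunConfig) -> dict:
    """Execute a full run and write every output table plus a manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    truths = None
    if config.mode == "simulate":
        base = default_params_calibrated()
        if config.noise_cv is not None:
            from dataclasses import replace
            base = replace(base, noise_cv=config.noise_cv)
        study, truths = simulate_cohort(base, config.n_per_group,
                                        config.weight_groups, seed=config.seed,
                                        mic=config.mic)
        write_study(study, config.out_dir)
        log.info("simulated %d subjects", len(study.subjects))
    else:
        study = load_study(config.inputs["doses"], config.inputs["dialysates"],
                           config.inputs["plasma"], config.inputs["catheters"],
                           config.inputs.get("subjects"), mic=config.mic)
        log.info("loaded %d subjects", len(study.subjects))

    res = analyze_study(study, config.mic, config.confidence_level,
                        config.lambda_min_points, config.study_end)
    out_tables = {
        "recoveries": recoveries_frame(res["recoveries"]),
        "profiles": profiles_frame(res["profiles"]),
        "nca_results": res["nca"],
        "pd_results": res["pd"],
        "summary_table1": res["tables"]["table1_weight_groups"],
        "summary_table2": res["tables"]["table2_ft_above_mic"],
        "summary_table2_comparisons": res["tables"]["table2_comparisons"],
        "summary_table3": res["tables"]["table3_time_to_threshold"],
        "summary_table4": res["tables"]["table4_pk_parameters"],
    }
    if truths is not None:
        out_tables["ground_truth"] = ground_truth_frame(truths)
    paths = write_results(out_tables, config.out_dir)

    for w in res["warnings"]:
        log.warning("%s", w)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_subjects": len(study.subjects),
        "outputs": {k: os.path.basename(v) for k, v in sorted(paths.items())},
        "warnings": res["warnings"],
        "statistics_note": res["tables"]["metadata"]["statistics"],
        "errors": [],
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def mic_sweep(study: CohortStudy, mic_list: Sequence[float],
              study_end: float = 960.0) -> pd.DataFrame:
    """PD results stacked over a list of MICs (fT>MIC is non-increasing in MIC)."""
    if not mic_list:
        raise ConfigError("mic_list must be non-empty")
    if any(m <= 0 for m in mic_list):
        raise ConfigError("all MIC values must be > 0")
    frames = []
    for mic in mic_list:
        res = analyze_study(study, mic=mic, study_end=study_end)
        df = res["pd"].copy()
        df.insert(0, "mic", mic)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
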