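"""End-to-end orchestration: parsed records -> screened set -> effect
sizes -> per-level random-effects fits -> classification grid and
threshold table.

This module is the library face of the whole procedure; the CLI is a thin
wrapper around :func:`run_analyze`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import carbonate, summary_convert
from .effect_size import effect_variance, log_response_ratio
from .ingest import (
    AMBIENT_MARKER,
    DEFAULT_CATEGORIES,
    StudyRecord,
    TreatmentArm,
    assign_co2_category,
    identify_ambient,
    parse_study_table,
    select_arm_for_category,
)
from .screen import (
    DEFAULT_AMBIENT_CUTOFF,
    DEFAULT_AMBIENT_TOLERANCE,
    DEFAULT_MAX_DAYS,
    exclusions_to_frame,
    screen_records,
)
from .thresholds import (
    DEFAULT_LOW_K_CUTOFF,
    classification_grid,
    summarize_groups,
    threshold_table,
)

__all__ = [
    "AnalysisConfig",
    "convert_records",
    "resolve_record",
    "compute_effects",
    "run_analyze",
]


@dataclass
class AnalysisConfig:
    """Every numeric choice that affects results, in one place."""

    variance_mode: str = "paper_literal"  # or "hedges"
    se_mode: str = "paper_literal"  # or "corrected" (quartile conversion)
    weights: str = "inverse_variance"  # or "equal"
    constants_set: str = "mehrbach_dm87"  # or "lueker2000"
    default_ph_scale: str = "total"
    ambient_reference: float = 400.0
    ambient_cutoff: float = DEFAULT_AMBIENT_CUTOFF
    ambient_tolerance: float = DEFAULT_AMBIENT_TOLERANCE
    ambient_band: float = 0.10
    max_days: float = DEFAULT_MAX_DAYS
    low_k_cutoff: int = DEFAULT_LOW_K_CUTOFF
    levels: Tuple[int, ...] = (1, 2, 3, 4)

    def to_dict(self) -> dict:
        return {
            "variance_mode": self.variance_mode,
            "se_mode": self.se_mode,
            "weights": self.weights,
            "constants_set": self.constants_set,
            "default_ph_scale": self.default_ph_scale,
            "ambient_reference": self.ambient_reference,
            "ambient_cutoff": self.ambient_cutoff,
            "ambient_tolerance": self.ambient_tolerance,
            "ambient_band": self.ambient_band,
            "max_days": self.max_days,
            "low_k_cutoff": self.low_k_cutoff,
            "levels": list(self.levels),
        }


def _converted_arm(arm: TreatmentArm, config: AnalysisConfig) -> TreatmentArm:
    """Fill in pCO2 from pH and mean/SE from quartiles where needed."""
    updates = {}
    if arm.co2_uatm is None and arm.ph is not None:
        state = carbonate.CarbonateState(
            temperature=arm.temperature_c,
            salinity=arm.salinity_psu,
            ph=arm.ph,
            ph_scale=arm.ph_scale or config.default_ph_scale,
            alkalinity=arm.alkalinity_umol_kg,
            dic=None if arm.alkalinity_umol_kg is not None else arm.dic_umol_kg,
            constants_set=config.constants_set,
        )
        updates["co2_uatm"] = carbonate.solve_pco2(state)
    if arm.mean is None and arm.has_quartiles:
        qs = summary_convert.QuartileSummary(
            q1=arm.q1, median=arm.median, q3=arm.q3, n=arm.n
        )
        updates["mean"] = summary_convert.estimate_mean(qs)
        updates["se"] = summary_convert.estimate_dispersion(qs, mode=config.se_mode)
    if not updates:
        return arm
    return arm.model_copy(update=updates)


def convert_records(
    records: Sequence[StudyRecord], config: Optional[AnalysisConfig] = None
) -> Tuple[List[StudyRecord], List[dict]]:
    """Resolve pH-reported arms to pCO2 and quartile summaries to
    mean/SE for every record; records whose chemistry cannot be solved
    are returned separately as audit entries."""
    config = config or AnalysisConfig()
    converted, failures = [], []
    for rec in records:
        try:
            arms = [_converted_arm(a, config) for a in rec.arms]
            converted.append(rec.model_copy(update={"arms": arms}))
        except (ArithmeticError, ValueError) as exc:
            failures.append(
                {
                    "record_id": rec.record_id,
                    "rule": "carbonate",
                    "reason": str(exc),
                    "parameters": f"constants_set={config.constants_set}",
                }
            )
    return converted, failures


def resolve_record(
    record: StudyRecord, config: AnalysisConfig
) -> Tuple[StudyRecord, TreatmentArm, Dict[str, TreatmentArm]]:
    """Convert all arms, identify the control, and bin treatments.

    Returns (converted record, control arm, {category label: selected arm}).
    """
    arms = [_converted_arm(a, config) for a in record.arms]
    rec = record.model_copy(update={"arms": arms})
    control = identify_ambient(arms, config.ambient_reference)
    by_cat: Dict[str, List[TreatmentArm]] = {}
    for arm in arms:
        if arm is control:
            continue
        label = assign_co2_category(
            arm.co2_uatm,
            control.co2_uatm,
            DEFAULT_CATEGORIES,
            ambient_band=config.ambient_band,
        )
        if label == AMBIENT_MARKER:
            continue
        by_cat.setdefault(label, []).append(arm)
    selected = {
        label: select_arm_for_category(arms_in_cat, label)
        for label, arms_in_cat in by_cat.items()
    }
    return rec, control, selected


def compute_effects(
    records: Sequence[StudyRecord], config: Optional[AnalysisConfig] = None
) -> Tuple[pd.DataFrame, List[dict]]:
    """Effect-size table from screened records.

    One row per (record x CO2 category) with signed LnRR, variance v and
    inverse-variance weight.  Effects with v = 0 (both dispersions zero)
    are routed to the audit list instead: 1/v is undefined, so they cannot
    enter weighted pooling.
    """
    config = config or AnalysisConfig()
    rows = []
    audit = []
    for record in records:
        rec, control, selected = resolve_record(record, config)
        for label, arm in sorted(selected.items()):
            lnrr = log_response_ratio(arm.mean, control.mean, rec.direction)
            v = effect_variance(
                arm.mean, arm.se, arm.n, control.mean, control.se, control.n,
                mode=config.variance_mode,
            )
            if v == 0.0:
                audit.append(
                    {
                        "record_id": rec.record_id,
                        "category": label,
                        "reason": "zero effect variance; excluded from weighted pooling",
                    }
                )
                continue
            rows.append(
                {
                    "study_id": rec.study_id,
                    "experiment_id": rec.experiment_id,
                    "species": rec.species,
                    "trophic_level": rec.trophic_level,
                    "group": rec.group,
                    "response_name": rec.response_name,
                    "community_flag": rec.community_flag,
                    "category": label,
                    "lnrr": lnrr,
                    "v": v,
                    "weight": 1.0 / v,
                }
            )
    columns = [
        "study_id", "experiment_id", "species", "trophic_level", "group",
        "response_name", "community_flag", "category", "lnrr", "v", "weight",
    ]
    return pd.DataFrame(rows, columns=columns), audit


def run_analyze(
    input_csv,
    out_dir,
    config: Optional[AnalysisConfig] = None,
    schema_config: Optional[dict] = None,
) -> Dict[str, Path]:
    """Full pipeline on a study-record CSV; writes all result artifacts.

    Outputs (all CSV/JSON) land in ``out_dir``: the effect-size table,
    one fit/classification grid per grouping level, one threshold table
    per level, the exclusion audit, and a run log with every parameter.
    Returns the mapping of artifact names to paths.
    """
    config = config or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}

    records = parse_study_table(input_csv, schema_config)
    # Ambient screening needs resolved pCO2, so convert up front.
    converted, conversion_failures = convert_records(records, config)
    kept, exclusions = screen_records(
        converted,
        max_days=config.max_days,
        ambient_cutoff=config.ambient_cutoff,
        tolerance=config.ambient_tolerance,
        ambient_reference=config.ambient_reference,
    )
    audit_df = exclusions_to_frame(exclusions)
    if conversion_failures:
        audit_df = pd.concat(
            [pd.DataFrame(conversion_failures), audit_df], ignore_index=True
        )

    effects, effect_audit = compute_effects(kept, config)
    for entry in effect_audit:
        audit_df.loc[len(audit_df)] = {
            "record_id": entry["record_id"],
            "rule": "effect_size",
            "reason": entry["reason"],
            "parameters": f"category={entry['category']}",
        }

    effects_path = out / "effect_sizes.csv"
    effects.to_csv(effects_path, index=False)
    artifacts["effect_sizes"] = effects_path

    audit_path = out / "exclusion_audit.csv"
    audit_df.to_csv(audit_path, index=False)
    artifacts["exclusion_audit"] = audit_path

    for level in config.levels:
        summaries = summarize_groups(effects, level, weights=config.weights)
        grid = classification_grid(summaries, config.low_k_cutoff)
        thr = threshold_table(summaries, config.low_k_cutoff)
        gpath = out / f"classification_level{level}.csv"
        tpath = out / f"thresholds_level{level}.csv"
        grid.to_csv(gpath, index=False)
        thr.to_csv(tpath, index=False)
        artifacts[f"classification_level{level}"] = gpath
        artifacts[f"thresholds_level{level}"] = tpath

    log = {
        "config": config.to_dict(),
        "n_records_parsed": len(records),
        "n_records_kept": len(kept),
        "n_excluded": int(len(audit_df)),
        "n_effects": int(len(effects)),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    artifacts["run_log"] = log_path
    return artifacts
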