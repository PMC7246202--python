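"""Inclusion/exclusion screening of study records with an audit trail.

Three filters mirror the selection rules of short-term ocean-acidification
meta-analysis: drop long-term acclimation studies (duration beyond about a
month), drop records whose co-stressors (temperature, light, nutrients)
were not at ambient levels, and drop records whose ambient/control CO2
treatment substantially exceeds the ~500 μatm present-day ceiling.

Every excluded record carries exactly one machine-readable reason code
plus the rule parameters in force at the time, so the audit CSV fully
explains the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import pandas as pd

from .ingest import StudyRecord, identify_ambient

__all__ = [
    "Exclusion",
    "filter_duration",
    "filter_costressor",
    "filter_ambient_control",
    "screen_records",
    "exclusions_to_frame",
    "DEFAULT_MAX_DAYS",
    "DEFAULT_AMBIENT_CUTOFF",
    "DEFAULT_AMBIENT_TOLERANCE",
]

DEFAULT_MAX_DAYS = 31.0
DEFAULT_AMBIENT_CUTOFF = 500.0
DEFAULT_AMBIENT_TOLERANCE = 0.10


@dataclass(frozen=True)
class Exclusion:
    record: StudyRecord
    rule: str
    reason: str
    parameters: str  # snapshot of the rule parameters, e.g. "max_days=31"


def filter_duration(
    records: Sequence[StudyRecord], max_days: float = DEFAULT_MAX_DAYS
) -> Tuple[List[StudyRecord], List[Exclusion]]:
    """Keep records with duration_days <= max_days.

    Records with no stated duration are excluded with their own reason
    code rather than silently kept.
    """
    kept, excluded = [], []
    params = f"max_days={max_days:g}"
    for rec in records:
        if rec.duration_days is None:
            excluded.append(Exclusion(rec, "duration", "missing duration", params))
        elif rec.duration_days <= max_days:
            kept.append(rec)
        else:
            excluded.append(
                Exclusion(rec, "duration", "long-term acclimation study", params)
            )
    return kept, excluded


def filter_costressor(
    records: Sequence[StudyRecord],
) -> Tuple[List[StudyRecord], List[Exclusion]]:
    """Keep records whose other stressors were all at ambient levels."""
    kept, excluded = [], []
    for rec in records:
        if rec.costressors_ambient:
            kept.append(rec)
        else:
            excluded.append(
                Exclusion(rec, "costressor", "co-stressor not at ambient", "")
            )
    return kept, excluded


def filter_ambient_control(
    records: Sequence[StudyRecord],
    ambient_cutoff: float = DEFAULT_AMBIENT_CUTOFF,
    tolerance: float = DEFAULT_AMBIENT_TOLERANCE,
    ambient_reference: float = 400.0,
) -> Tuple[List[StudyRecord], List[Exclusion]]:
    """Keep records whose control arm pCO2 is at most cutoff*(1+tolerance).

    The control arm is the flagged one or the arm closest to the ambient
    reference.  Records whose control arm has no resolved pCO2 (pH not yet
    converted) are excluded with a "cannot convert" reason.
    """
    kept, excluded = [], []
    params = f"ambient_cutoff={ambient_cutoff:g},tolerance={tolerance:g}"
    limit = ambient_cutoff * (1.0 + tolerance)
    for rec in records:
        arms = [a for a in rec.arms if a.co2_uatm is not None]
        if not arms:
            excluded.append(
                Exclusion(rec, "ambient_control", "cannot convert CO2 level", params)
            )
            continue
        control = identify_ambient(arms, ambient_reference)
        if control.co2_uatm <= limit:
            kept.append(rec)
        else:
            excluded.append(
                Exclusion(
                    rec,
                    "ambient_control",
                    "ambient treatment substantially exceeds cutoff",
                    params,
                )
            )
    return kept, excluded


def screen_records(
    records: Sequence[StudyRecord],
    max_days: float = DEFAULT_MAX_DAYS,
    ambient_cutoff: float = DEFAULT_AMBIENT_CUTOFF,
    tolerance: float = DEFAULT_AMBIENT_TOLERANCE,
    ambient_reference: float = 400.0,
) -> Tuple[List[StudyRecord], List[Exclusion]]:
    """Run all filters in the fixed order duration -> costressor -> ambient.

    The kept set is order-invariant; the fixed order only makes the audit
    trail deterministic.
    """
    kept, all_excluded = filter_duration(records, max_days)
    kept, excl = filter_costressor(kept)
    all_excluded += excl
    kept, excl = filter_ambient_control(kept, ambient_cutoff, tolerance, ambient_reference)
    all_excluded += excl
    return kept, all_excluded


def exclusions_to_frame(exclusions: Sequence[Exclusion]) -> pd.DataFrame:
    """Audit trail as a DataFrame (record_id, rule, reason, parameters)."""
    return pd.DataFrame(
        [
            {
                "record_id": e.record.record_id,
                "rule": e.rule,
                "reason": e.reason,
                "parameters": e.parameters,
            }
            for e in exclusions
        ],
        columns=["record_id", "rule", "reason", "parameters"],
    )
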