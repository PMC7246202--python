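"""Read, validate and resolve the study-record table.

The input is a flat CSV with one row per treatment arm; rows sharing
(study_id, experiment_id, species, response_name) form one study record.
Each arm reports either its pCO2 directly (μatm) or a pH with the
auxiliary chemistry needed to solve for pCO2, and either mean/SE/n or a
median/quartile summary.

Resolution turns a record's arms into (control, treatment-per-CO2-category)
pairs: the ambient/control arm is the flagged control if one exists,
otherwise the arm closest to the ambient reference (ties toward lower
CO2); remaining arms are binned into the CO2 categories and, within a
category holding several arms, the highest treatment is used — except in
the pre-industrial category, where the lowest is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "TreatmentArm",
    "StudyRecord",
    "CO2Category",
    "DEFAULT_CATEGORIES",
    "AMBIENT_MARKER",
    "GROUP_TROPHIC",
    "ARM_COLUMNS",
    "parse_study_table",
    "write_study_table",
    "assign_co2_category",
    "select_arm_for_category",
    "identify_ambient",
    "SchemaError",
    "RowValidationError",
]

GROUP_TROPHIC = {
    "bacteria": "prokaryote",
    "phytoplankton": "autotroph",
    "macroalgae": "autotroph",
    "invertebrate": "heterotroph",
    "fish": "heterotroph",
}

AMBIENT_MARKER = "ambient"


class SchemaError(ValueError):
    """The CSV is missing required columns."""


class RowValidationError(ValueError):
    """One or more rows failed validation; message lists row and field."""


class TreatmentArm(BaseModel):
    """One treatment arm: CO2 descriptor plus a response summary.

    Exactly one of {mean+se, q1+median+q3} must be present on input; after
    summary conversion every arm carries mean and se.  If co2_uatm is
    absent, ph plus the auxiliary chemistry (temperature, salinity, and
    alkalinity or DIC) must be present so pCO2 can be solved.
    """

    co2_uatm: Optional[float] = None
    ph: Optional[float] = None
    ph_scale: Optional[str] = None
    temperature_c: Optional[float] = None
    salinity_psu: Optional[float] = None
    alkalinity_umol_kg: Optional[float] = None
    dic_umol_kg: Optional[float] = None
    mean: Optional[float] = None
    se: Optional[float] = None
    n: int
    q1: Optional[float] = None
    median: Optional[float] = None
    q3: Optional[float] = None
    is_control: bool = False

    @model_validator(mode="after")
    def _check(self) -> "TreatmentArm":
        if self.n < 1:
            raise ValueError("n must be >= 1")
        has_mean = self.mean is not None and self.se is not None
        has_quart = all(x is not None for x in (self.q1, self.median, self.q3))
        if has_mean == has_quart:
            raise ValueError(
                "exactly one of {mean+se, q1+median+q3} must be present"
            )
        if has_quart and not (self.q1 <= self.median <= self.q3):
            raise ValueError(
                f"quartiles out of order: q1={self.q1}, median={self.median}, q3={self.q3}"
            )
        if self.co2_uatm is None:
            aux = (
                self.ph is not None
                and self.temperature_c is not None
                and self.salinity_psu is not None
                and (self.alkalinity_umol_kg is not None or self.dic_umol_kg is not None)
            )
            if not aux:
                raise ValueError(
                    "arm reports neither co2_uatm nor pH with auxiliary "
                    "chemistry (temperature, salinity, alkalinity-or-DIC)"
                )
        elif self.co2_uatm <= 0:
            raise ValueError(f"co2_uatm must be positive, got {self.co2_uatm}")
        return self

    @property
    def has_quartiles(self) -> bool:
        return self.q1 is not None and self.median is not None and self.q3 is not None


class StudyRecord(BaseModel):
    """One study x experiment x species x response with all its arms."""

    study_id: str
    experiment_id: str
    species: str
    group: Literal["bacteria", "phytoplankton", "macroalgae", "invertebrate", "fish"]
    trophic_level: Literal["prokaryote", "autotroph", "heterotroph"]
    response_name: str
    direction: Literal["higher_is_better", "higher_is_worse"]
    community_flag: Literal["single_species", "community"] = "single_species"
    duration_days: Optional[float] = None
    costressors_ambient: bool = True
    arms: List[TreatmentArm]

    @model_validator(mode="after")
    def _check(self) -> "StudyRecord":
        if len(self.arms) < 2:
            raise ValueError("a study record needs at least 2 arms")
        if GROUP_TROPHIC[self.group] != self.trophic_level:
            raise ValueError(
                f"group {self.group!r} is inconsistent with trophic level "
                f"{self.trophic_level!r} (expected {GROUP_TROPHIC[self.group]!r})"
            )
        if sum(a.is_control for a in self.arms) > 1:
            raise ValueError("at most one arm may be flagged as control")
        return self

    @property
    def record_id(self) -> str:
        return f"{self.study_id}/{self.experiment_id}/{self.species}/{self.response_name}"


@dataclass(frozen=True)
class CO2Category:
    """A half-open (lower, upper] pCO2 band with a display label."""

    label: str
    lower: float
    upper: float

    def contains(self, co2_uatm: float) -> bool:
        return self.lower < co2_uatm <= self.upper


# The treatment bands used throughout: a sub-ambient pre-industrial band
# plus five elevated bands partitioning (500, inf).  The integer display
# names ("801-1,000") are labels; bounds are real-valued and half-open.
PREINDUSTRIAL_UPPER = 300.0

DEFAULT_CATEGORIES: Tuple[CO2Category, ...] = (
    CO2Category("preindustrial", 0.0, PREINDUSTRIAL_UPPER),
    CO2Category("c500_800", 500.0, 800.0),
    CO2Category("c801_1000", 800.0, 1000.0),
    CO2Category("c1001_1500", 1000.0, 1500.0),
    CO2Category("c1501_2000", 1500.0, 2000.0),
    CO2Category("gt2000", 2000.0, math.inf),
)

CATEGORY_DISPLAY = {
    "preindustrial": "pre-industrial",
    "c500_800": "500-800",
    "c801_1000": "801-1,000",
    "c1001_1500": "1,001-1,500",
    "c1501_2000": "1,501-2,000",
    "gt2000": ">2,000",
}


def assign_co2_category(
    co2_uatm: float,
    ambient_uatm: float,
    categories: Sequence[CO2Category] = DEFAULT_CATEGORIES,
    ambient_band: float = 0.10,
) -> str:
    """Bin a treatment pCO2 into a category label or the ambient marker.

    Values within ``ambient_band`` (relative) of the ambient reference are
    the ambient marker.  Sub-ambient values below the pre-industrial upper
    bound — and any value below ambient that falls in no elevated band —
    map to the pre-industrial category.  Returns a category label string.
    """
    if co2_uatm <= 0:
        raise ValueError(f"co2_uatm must be positive, got {co2_uatm}")
    if abs(co2_uatm - ambient_uatm) <= ambient_band * ambient_uatm:
        return AMBIENT_MARKER
    if co2_uatm < ambient_uatm:
        return "preindustrial"
    for cat in categories:
        if cat.label == "preindustrial":
            continue
        if cat.contains(co2_uatm):
            return cat.label
    # Above ambient but below the lowest elevated band: treat as ambient.
    return AMBIENT_MARKER


def select_arm_for_category(
    arms: Sequence[TreatmentArm], category: str
) -> TreatmentArm:
    """Pick the arm used for a category holding several treatments.

    Highest pCO2 wins, except in the pre-industrial category where the
    lowest is used.  Order-independent and idempotent.
    """
    if not arms:
        raise ValueError("select_arm_for_category requires a non-empty arm list")
    key = lambda a: (a.co2_uatm, id(a))  # noqa: E731 - stable tie-break
    if category == "preindustrial":
        return min(arms, key=lambda a: a.co2_uatm)
    return max(arms, key=lambda a: a.co2_uatm)


def identify_ambient(
    arms: Sequence[TreatmentArm], ambient_reference: float = 400.0
) -> TreatmentArm:
    """The control arm: the flagged one if present, else the arm closest
    to the ambient reference, ties broken toward lower CO2."""
    if not arms:
        raise ValueError("identify_ambient requires a non-empty arm list")
    for arm in arms:
        if arm.is_control:
            return arm
    return min(arms, key=lambda a: (abs(a.co2_uatm - ambient_reference), a.co2_uatm))


# ---------------------------------------------------------------------------
# CSV I/O

ARM_COLUMNS = [
    "study_id",
    "experiment_id",
    "species",
    "group",
    "trophic_level",
    "response_name",
    "direction",
    "community_flag",
    "duration_days",
    "costressors_ambient",
    "is_control",
    "co2_uatm",
    "ph",
    "ph_scale",
    "temperature_c",
    "salinity_psu",
    "alkalinity_umol_kg",
    "dic_umol_kg",
    "mean",
    "se",
    "n",
    "q1",
    "median",
    "q3",
]

REQUIRED_COLUMNS = [
    "study_id",
    "experiment_id",
    "species",
    "group",
    "trophic_level",
    "response_name",
    "direction",
    "n",
]

RECORD_KEY = ["study_id", "experiment_id", "species", "response_name"]

_NUMERIC_FIELDS = [
    "duration_days",
    "co2_uatm",
    "ph",
    "temperature_c",
    "salinity_psu",
    "alkalinity_umol_kg",
    "dic_umol_kg",
    "mean",
    "se",
    "q1",
    "median",
    "q3",
]

_BOOL_TRUE = {"true", "1", "yes", "y"}
_BOOL_FALSE = {"false", "0", "no", "n", ""}


def _opt_float(raw, row_no: int, field_name: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowValidationError(
            f"row {row_no}: field {field_name!r} is not numeric: {raw!r}"
        ) from None


def _opt_str(raw) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    return str(raw)


def _opt_bool(raw, row_no: int, field_name: str, default: bool) -> bool:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return default
    s = str(raw).strip().lower()
    if s in _BOOL_TRUE:
        return True
    if s in _BOOL_FALSE:
        return default if s == "" else False
    raise RowValidationError(f"row {row_no}: field {field_name!r} is not boolean: {raw!r}")


def parse_study_table(path, schema_config: Optional[dict] = None) -> List[StudyRecord]:
    """Parse a study-record CSV into validated StudyRecords.

    ``schema_config`` optionally maps canonical column names to the names
    used in the file (``{"co2_uatm": "pCO2"}``).  Rows are grouped into
    records on (study_id, experiment_id, species, response_name).  Any
    validation failure raises with the offending CSV row number (header =
    row 1) and field named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if schema_config:
        rename = {src: canon for canon, src in schema_config.items() if src in df.columns}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    rows = []
    errors = []
    for i, row in df.iterrows():
        row_no = i + 2  # header is row 1
        try:
            n_raw = row.get("n")
            try:
                n = int(float(n_raw))
            except (TypeError, ValueError):
                raise RowValidationError(
                    f"row {row_no}: field 'n' is not an integer: {n_raw!r}"
                ) from None
            arm = TreatmentArm(
                co2_uatm=_opt_float(row.get("co2_uatm"), row_no, "co2_uatm"),
                ph=_opt_float(row.get("ph"), row_no, "ph"),
                ph_scale=_opt_str(row.get("ph_scale")),
                temperature_c=_opt_float(row.get("temperature_c"), row_no, "temperature_c"),
                salinity_psu=_opt_float(row.get("salinity_psu"), row_no, "salinity_psu"),
                alkalinity_umol_kg=_opt_float(
                    row.get("alkalinity_umol_kg"), row_no, "alkalinity_umol_kg"
                ),
                dic_umol_kg=_opt_float(row.get("dic_umol_kg"), row_no, "dic_umol_kg"),
                mean=_opt_float(row.get("mean"), row_no, "mean"),
                se=_opt_float(row.get("se"), row_no, "se"),
                n=n,
                q1=_opt_float(row.get("q1"), row_no, "q1"),
                median=_opt_float(row.get("median"), row_no, "median"),
                q3=_opt_float(row.get("q3"), row_no, "q3"),
                is_control=_opt_bool(row.get("is_control"), row_no, "is_control", False),
            )
        except RowValidationError as exc:
            errors.append(str(exc))
            continue
        except ValueError as exc:
            errors.append(f"row {row_no}: {exc}")
            continue
        meta = {c: row.get(c) for c in RECORD_KEY}
        meta.update(
            group=row.get("group"),
            trophic_level=row.get("trophic_level"),
            direction=row.get("direction"),
            community_flag=_opt_str(row.get("community_flag")) or "single_species",
            duration_days=_opt_float(row.get("duration_days"), row_no, "duration_days"),
            costressors_ambient=_opt_bool(
                row.get("costressors_ambient"), row_no, "costressors_ambient", True
            ),
        )
        rows.append((row_no, meta, arm))
    if errors:
        raise RowValidationError("; ".join(errors))

    records: List[StudyRecord] = []
    seen = {}
    order = []
    for row_no, meta, arm in rows:
        key = tuple(meta[c] for c in RECORD_KEY)
        if key not in seen:
            seen[key] = {"meta": meta, "arms": [], "rows": []}
            order.append(key)
        seen[key]["arms"].append(arm)
        seen[key]["rows"].append(row_no)
    for key in order:
        bundle = seen[key]
        meta = bundle["meta"]
        try:
            records.append(StudyRecord(arms=bundle["arms"], **meta))
        except ValueError as exc:
            raise RowValidationError(
                f"rows {bundle['rows']}: record {key} invalid: {exc}"
            ) from None
    return records


def records_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Flatten StudyRecords back to the one-row-per-arm table."""
    out = []
    for rec in records:
        for arm in rec.arms:
            row = {
                "study_id": rec.study_id,
                "experiment_id": rec.experiment_id,
                "species": rec.species,
                "group": rec.group,
                "trophic_level": rec.trophic_level,
                "response_name": rec.response_name,
                "direction": rec.direction,
                "community_flag": rec.community_flag,
                "duration_days": rec.duration_days,
                "costressors_ambient": rec.costressors_ambient,
                "is_control": arm.is_control,
                "co2_uatm": arm.co2_uatm,
                "ph": arm.ph,
                "ph_scale": arm.ph_scale,
                "temperature_c": arm.temperature_c,
                "salinity_psu": arm.salinity_psu,
                "alkalinity_umol_kg": arm.alkalinity_umol_kg,
                "dic_umol_kg": arm.dic_umol_kg,
                "mean": arm.mean,
                "se": arm.se,
                "n": arm.n,
                "q1": arm.q1,
                "median": arm.median,
                "q3": arm.q3,
            }
            out.append(row)
    return pd.DataFrame(out, columns=ARM_COLUMNS)


def write_study_table(records: Sequence[StudyRecord], path) -> None:
    """Write records as the canonical one-row-per-arm CSV (UTF-8, comma,
    '.' decimal), with floats at full repr precision for bit-exact
    round-trips."""
    df = records_to_frame(records)
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def write_jsonl(records: Sequence[StudyRecord], path) -> None:
    """Write records as JSON-lines, one StudyRecord per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.model_dump_json() + "\n")
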