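"""Patient-level domain model for secondary-prevention ASCVD cohorts.

A cohort is a list of :class:`PatientRecord` objects, one per patient with
established atherosclerotic cardiovascular disease (ASCVD).  Each record
carries the covariates consumed by the 20-month recurrent-event risk
equation (age, sex, smoking, diabetes, blood pressure, ...), the LDL-C
concentration in mg/dl, the vascular-bed subtype used for stratified
reporting (coronary / cerebrovascular / peripheral — one mutually exclusive
category per patient, the most recent manifestation), and the
lipid-lowering-therapy (LLT) regimen at the time of LDL-C measurement.

Cohorts round-trip losslessly through a plain CSV format (UTF-8, comma
separated, header required, booleans serialized as 0/1).
"""

from __future__ import annotations

import enum
import logging
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AscvdSubtype",
    "Sex",
    "Smoking",
    "StatinIntensity",
    "LLTCategory",
    "LLTRegimen",
    "PatientRecord",
    "COHORT_COLUMNS",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
    "classify_llt",
    "goal_attainment",
]


class CohortError(ValueError):
    """Raised for unreadable, empty or schema-invalid cohort files."""


class AscvdSubtype(str, enum.Enum):
    """Most recent manifestation of vascular disease (mutually exclusive)."""

    CAD = "CAD"  # coronary artery disease
    CBD = "CBD"  # cerebrovascular disease
    PAD = "PAD"  # peripheral artery disease


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Smoking(str, enum.Enum):
    non = "non"
    ex = "ex"
    light = "light"
    moderate = "moderate"
    heavy = "heavy"


class StatinIntensity(str, enum.Enum):
    none = "none"
    low = "low"
    moderate = "moderate"
    high = "high"
    unknown = "unknown"


class LLTCategory(str, enum.Enum):
    """Mutually exclusive, exhaustive therapy categories for treated patients."""

    low_statin_mono = "low_statin_mono"
    moderate_statin_mono = "moderate_statin_mono"
    high_statin_mono = "high_statin_mono"
    ezetimibe_combo = "ezetimibe_combo"
    pcsk9i_combo = "pcsk9i_combo"
    other_llt = "other_llt"


class LLTRegimen(BaseModel):
    """Lipid-lowering therapy at LDL-C measurement."""

    model_config = {"frozen": True}

    statin_intensity: StatinIntensity = StatinIntensity.none
    ezetimibe: bool = False
    pcsk9i: bool = False
    other_llt: bool = False

    @property
    def any_therapy(self) -> bool:
        return (
            self.statin_intensity is not StatinIntensity.none
            or self.ezetimibe
            or self.pcsk9i
            or self.other_llt
        )


class PatientRecord(BaseModel):
    """One ASCVD patient: risk-equation covariates, LDL-C, subtype, LLT."""

    model_config = {"frozen": True}

    patient_id: str
    ascvd_subtype: AscvdSubtype
    ldl_c: float = Field(gt=0, description="LDL cholesterol, mg/dl")
    age: float = Field(ge=18, le=110, description="years")
    sex: Sex
    smoking: Smoking
    diabetes: bool
    hypertension: bool
    chf: bool
    af: bool
    sbp: float = Field(gt=0, description="systolic blood pressure, mmHg")
    dbp: float = Field(gt=0, description="diastolic blood pressure, mmHg")
    bmi: float = Field(gt=0, description="kg/m^2")
    ckd_ge3: bool
    n_vascular_beds: int = Field(ge=1, le=3)
    event_within_1y: bool
    region: str
    llt: LLTRegimen


# Stable on-disk column order; `llt` is flattened into its four fields.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "ascvd_subtype",
    "ldl_c",
    "age",
    "sex",
    "smoking",
    "diabetes",
    "hypertension",
    "chf",
    "af",
    "sbp",
    "dbp",
    "bmi",
    "ckd_ge3",
    "n_vascular_beds",
    "event_within_1y",
    "region",
    "statin_intensity",
    "ezetimibe",
    "pcsk9i",
    "other_llt",
)

_BOOL_COLUMNS = (
    "diabetes",
    "hypertension",
    "chf",
    "af",
    "ckd_ge3",
    "event_within_1y",
    "ezetimibe",
    "pcsk9i",
    "other_llt",
)


def _record_to_row(record: PatientRecord) -> dict:
    row = record.model_dump(mode="json", exclude={"llt"})
    row.update(record.llt.model_dump(mode="json"))
    for col in _BOOL_COLUMNS:
        row[col] = int(row[col])
    return row


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame with the canonical column order."""
    frame = pd.DataFrame([_record_to_row(r) for r in records], columns=list(COHORT_COLUMNS))
    return frame


def _row_to_record(row: dict) -> PatientRecord:
    llt = LLTRegimen(
        statin_intensity=row["statin_intensity"],
        ezetimibe=bool(int(row["ezetimibe"])),
        pcsk9i=bool(int(row["pcsk9i"])),
        other_llt=bool(int(row["other_llt"])),
    )
    fields = {k: row[k] for k in COHORT_COLUMNS if k not in LLTRegimen.model_fields}
    for col in _BOOL_COLUMNS:
        if col in fields:
            fields[col] = bool(int(fields[col]))
    return PatientRecord(llt=llt, **fields)


def frame_to_records(
    frame: pd.DataFrame, on_invalid: Literal["error", "skip"] = "error"
) -> list[PatientRecord]:
    """Validate a flat cohort DataFrame row by row.

    With ``on_invalid="skip"`` a row that fails validation is excluded and
    reported (row index and reason) through the module logger; with
    ``"error"`` the first failure raises :class:`CohortError`.
    """
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortError(f"cohort table is missing required columns: {missing}")
    records: list[PatientRecord] = []
    for idx, row in enumerate(frame.to_dict(orient="records")):
        try:
            records.append(_row_to_record(row))
        except (ValidationError, ValueError) as exc:
            msg = f"row {idx}: invalid patient record ({exc})"
            if on_invalid == "error":
                raise CohortError(msg) from exc
            logger.warning("excluding %s", msg)
    return records


def read_cohort(
    path: str | Path, on_invalid: Literal["error", "skip"] = "error"
) -> list[PatientRecord]:
    """Read a cohort CSV, validating every row.

    Raises :class:`CohortError` for a missing/empty file or missing columns.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort file not found: {path}")
    try:
        # round_trip parsing: write/read must be bit-identical for floats
        frame = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"cohort file is empty: {path}") from exc
    return frame_to_records(frame, on_invalid=on_invalid)


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> Path:
    """Write records as CSV with the canonical column order.

    ``read_cohort(write_cohort(x)) == x`` field for field; an empty record
    list produces a header-only file.
    """
    path = Path(path)
    frame = records_to_frame(list(records))
    frame.to_csv(path, index=False)
    return path


def classify_llt(regimen: LLTRegimen) -> LLTCategory:
    """Assign a treated regimen to its mutually exclusive therapy category.

    Precedence: PCSK9i-containing *combinations* first, then ezetimibe plus a
    moderate/high/unknown-intensity statin, then statin monotherapies by
    intensity; everything else (ezetimibe alone or with a low-intensity
    statin, PCSK9i alone, unknown-intensity statin monotherapy, non-statin
    agents such as fibrates) falls into ``other_llt``.
    """
    if not regimen.any_therapy:
        raise ValueError("regimen has no lipid-lowering therapy (cohort requires treated patients)")
    statin = regimen.statin_intensity
    on_statin = statin is not StatinIntensity.none
    if regimen.pcsk9i and (on_statin or regimen.ezetimibe):
        return LLTCategory.pcsk9i_combo
    if regimen.ezetimibe and statin in (
        StatinIntensity.moderate,
        StatinIntensity.high,
        StatinIntensity.unknown,
    ):
        return LLTCategory.ezetimibe_combo
    if on_statin and not regimen.ezetimibe and not regimen.pcsk9i:
        if statin is StatinIntensity.low:
            return LLTCategory.low_statin_mono
        if statin is StatinIntensity.moderate:
            return LLTCategory.moderate_statin_mono
        if statin is StatinIntensity.high:
            return LLTCategory.high_statin_mono
        return LLTCategory.other_llt  # unknown-intensity statin monotherapy
    return LLTCategory.other_llt


def goal_attainment(
    records: Sequence[PatientRecord], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Proportion of patients with LDL-C strictly below each threshold.

    Returns a tidy frame with one row per (group, threshold): the overall
    cohort, each ASCVD subtype, and each LLT category.  Proportions are in
    [0, 1] and monotone in the threshold.
    """
    if not records:
        raise CohortError("goal attainment is undefined for an empty cohort")
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be strictly positive")
    frame = pd.DataFrame(
        {
            "ldl_c": [r.ldl_c for r in records],
            "subtype": [r.ascvd_subtype.value for r in records],
            "llt_category": [classify_llt(r.llt).value for r in records],
        }
    )
    groups: list[tuple[str, str, pd.DataFrame]] = [("overall", "overall", frame)]
    groups += [("subtype", k, g) for k, g in frame.groupby("subtype", sort=True)]
    groups += [("llt_category", k, g) for k, g in frame.groupby("llt_category", sort=True)]
    rows = []
    for group_type, group, sub in groups:
        for t in thresholds:
            rows.append(
                {
                    "group_type": group_type,
                    "group": group,
                    "threshold": float(t),
                    "n": len(sub),
                    "proportion": float((sub["ldl_c"] < t).mean()),
                }
            )
    return pd.DataFrame(rows)
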