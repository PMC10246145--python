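"""Cohort data model, CSV I/O and variable derivation for case-control studies.

A cohort is a list of :class:`SubjectRecord` — one row per participant with
case/control status, demographics and binary exposure/feature indicators.
Exposure indicators are three-valued (:class:`TriBool`): *yes*, *no* and
*unknown* are distinct, and *unknown* is never coerced to *no*.  All analysis
routines work on the complete-case subset for the variables they use.

Two derivation rules produce the analysis-ready exposure variables for cases:

* events (head injury, pesticide exposure start) occurring in the same
  integer year as disease onset or later are not counted as events;
* a sensitivity recode additionally discards head-injury events within a
  configurable window (default 10 years) before onset.

Controls have no onset age and are never censored.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields as _dc_fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TriBool",
    "SubjectRecord",
    "DerivedVariables",
    "SchemaError",
    "RowParseError",
    "ValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "derive_variables",
    "complete_case_subset",
    "to_analysis_frame",
    "ANALYSIS_VARIABLES",
    "COLUMNS",
]


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class RowParseError(ValueError):
    """A data row carries an unparseable code; the message names the row."""


class ValidationError(ValueError):
    """A record (or set of records) violates a cohort invariant."""


class TriBool(Enum):
    """Three-valued indicator: yes / no / unknown, serialized as 1 / 0 / NA."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError(
            "TriBool is three-valued; compare against TriBool members explicitly"
        )

    @classmethod
    def from_cell(cls, cell: str) -> "TriBool":
        token = cell.strip().lower()
        if token in {"1", "yes", "y", "true"}:
            return cls.YES
        if token in {"0", "no", "n", "false"}:
            return cls.NO
        if token in {"", "na", "nan", "unknown", "don't know", "dont know", "dk"}:
            return cls.UNKNOWN
        raise ValueError(f"unparseable tri-state value {cell!r}")

    def to_cell(self) -> str:
        return {"yes": "1", "no": "0", "unknown": "NA"}[self.value]


_STATUS_CODES = {
    "case": "case", "pd": "case", "pwp": "case", "1": "case",
    "control": "control", "nhc": "control", "hc": "control", "0": "control",
}
_SEX_CODES = {
    "male": "male", "m": "male",
    "female": "female", "f": "female",
    "": "unknown", "na": "unknown", "unknown": "unknown",
}
_FH_CODES = {
    "1": "positive", "positive": "positive", "yes": "positive",
    "0": "negative", "negative": "negative", "no": "negative",
    "": "unknown", "na": "unknown", "nan": "unknown", "unknown": "unknown",
}


@dataclass
class SubjectRecord:
    """One participant: status, demographics, exposures and features.

    ``family_history`` is pre-coded {positive, negative, unknown} (positive =
    at least one first- or second-degree relative affected; an unspecified
    degree is unknown and excluded from analysis).
    """

    subject_id: str
    status: str  # "case" | "control"
    sex: str = "unknown"  # "male" | "female" | "unknown"
    age_years: float | None = None
    onset_age_years: float | None = None  # cases only
    family_history: str = "unknown"  # "positive" | "negative" | "unknown"
    mtbi: TriBool = TriBool.UNKNOWN
    mtbi_first_age_years: float | None = None
    repeated_blows: TriBool = TriBool.UNKNOWN
    pesticide: TriBool = TriBool.UNKNOWN
    pesticide_start_age_years: float | None = None
    pesticide_end_age_years: float | None = None
    agent_orange: TriBool = TriBool.UNKNOWN
    constipation: TriBool = TriBool.UNKNOWN
    rbd: TriBool = TriBool.UNKNOWN
    weight_loss: TriBool = TriBool.UNKNOWN
    race: str | None = None
    ethnicity: str | None = None

    def validate(self) -> "SubjectRecord":
        if self.status not in ("case", "control"):
            raise ValidationError(
                f"{self.subject_id}: status must be case/control, got {self.status!r}"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"{self.subject_id}: bad sex {self.sex!r}")
        if self.family_history not in ("positive", "negative", "unknown"):
            raise ValidationError(
                f"{self.subject_id}: bad family_history {self.family_history!r}"
            )
        for name in ("age_years", "onset_age_years", "mtbi_first_age_years",
                     "pesticide_start_age_years", "pesticide_end_age_years"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(
                    f"{self.subject_id}: {name} must be a non-negative real, got {v!r}"
                )
        if self.onset_age_years is not None:
            if self.status != "case":
                raise ValidationError(
                    f"{self.subject_id}: onset age given for a control"
                )
            if self.age_years is not None and self.onset_age_years > self.age_years:
                raise ValidationError(
                    f"{self.subject_id}: onset age exceeds current age"
                )
        if (self.pesticide_start_age_years is not None
                and self.pesticide_end_age_years is not None
                and self.pesticide_end_age_years < self.pesticide_start_age_years):
            raise ValidationError(
                f"{self.subject_id}: pesticide exposure ends before it starts"
            )
        return self


TRIBOOL_FIELDS = ("mtbi", "repeated_blows", "pesticide", "agent_orange",
                  "constipation", "rbd", "weight_loss")
_FLOAT_FIELDS = ("age_years", "onset_age_years", "mtbi_first_age_years",
                 "pesticide_start_age_years", "pesticide_end_age_years")

#: Canonical column order of the cohort CSV.
COLUMNS: tuple[str, ...] = tuple(f.name for f in _dc_fields(SubjectRecord))

#: Columns that must be present in every cohort CSV header.
REQUIRED_COLUMNS = ("subject_id", "status", "sex", "age_years")


def _parse_float(cell: str, what: str) -> float | None:
    token = cell.strip()
    if token.lower() in {"", "na", "nan", "unknown"}:
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"unparseable {what} {cell!r}") from exc


def _record_from_row(row: Mapping[str, str]) -> SubjectRecord:
    status_token = row["status"].strip().lower()
    if status_token not in _STATUS_CODES:
        raise ValueError(f"unparseable status code {row['status']!r}")
    sex_token = row.get("sex", "").strip().lower()
    if sex_token not in _SEX_CODES:
        raise ValueError(f"unparseable sex code {row['sex']!r}")
    kwargs: dict = {
        "subject_id": row["subject_id"].strip(),
        "status": _STATUS_CODES[status_token],
        "sex": _SEX_CODES[sex_token],
        "family_history": _FH_CODES.get(
            row.get("family_history", "").strip().lower()
        ),
    }
    if kwargs["family_history"] is None:
        raise ValueError(
            f"unparseable family_history code {row['family_history']!r}"
        )
    for name in _FLOAT_FIELDS:
        kwargs[name] = _parse_float(row.get(name, ""), name)
    for name in TRIBOOL_FIELDS:
        kwargs[name] = TriBool.from_cell(row.get(name, ""))
    for name in ("race", "ethnicity"):
        token = row.get(name, "").strip()
        kwargs[name] = token or None
    return SubjectRecord(**kwargs)


def read_cohort_csv(
    path: str | Path,
    header_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[SubjectRecord]:
    """Read a cohort CSV into validated :class:`SubjectRecord` objects.

    Blank, ``NA`` and ``unknown`` cells map to the unknown/absent state.
    ``header_map`` renames alternate headers to the canonical snake_case
    schema (``{"file header": "canonical_name"}``).

    Raises :class:`SchemaError` for a missing required column,
    :class:`RowParseError` (with the 1-based data row number) for a bad code,
    and :class:`ValidationError` for invariant violations or duplicate ids.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        fieldnames = [
            (header_map or {}).get(name, name).strip() for name in reader.fieldnames
        ]
        for required in REQUIRED_COLUMNS:
            if required not in fieldnames:
                raise SchemaError(f"{path}: missing required column {required!r}")
        records: list[SubjectRecord] = []
        seen_ids: set[str] = set()
        for i, raw in enumerate(reader, start=1):
            row = {name: (raw.get(orig) or "")
                   for name, orig in zip(fieldnames, reader.fieldnames)}
            try:
                record = _record_from_row(row).validate()
            except ValidationError:
                raise
            except ValueError as exc:
                raise RowParseError(f"{path}: row {i}: {exc}") from exc
            if record.subject_id in seen_ids:
                raise ValidationError(
                    f"{path}: duplicate subject_id {record.subject_id!r}"
                )
            seen_ids.add(record.subject_id)
            records.append(record)
    return records


def _format_float(v: float | None) -> str:
    if v is None:
        return ""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_cohort_csv(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write records under the canonical schema; re-reading reproduces them.

    TriBools are encoded 1/0/NA; absent reals as empty cells.  Output is
    byte-stable for a given record list (fixed field order and formatting).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COLUMNS)
        for record in records:
            row = []
            for name in COLUMNS:
                v = getattr(record, name)
                if isinstance(v, TriBool):
                    row.append(v.to_cell())
                elif name in _FLOAT_FIELDS:
                    row.append(_format_float(v))
                elif name == "family_history":
                    row.append({"positive": "1", "negative": "0", "unknown": "NA"}[v])
                elif v is None:
                    row.append("")
                else:
                    row.append(str(v))
            writer.writerow(row)


@dataclass
class DerivedVariables:
    """Analysis-ready variables after event censoring and recoding."""

    mtbi_precensored: TriBool
    mtbi_10yr: TriBool
    pesticide_precensored: TriBool
    pesticide_duration_years: float | None
    family_history_binary: bool | None


def derive_variables(
    record: SubjectRecord, ten_year_window: float = 10.0
) -> DerivedVariables:
    """Apply onset-linked censoring and recoding rules to one record.

    For cases, an MTBI first occurring in the same integer year as onset or
    later does not count as an event; the sensitivity recode
    (``mtbi_10yr``) additionally drops events within ``ten_year_window``
    years before onset.  Pesticide exposure starting at or after onset is
    likewise discounted.  Controls are never censored.  Ages compare on
    whole (floored) years since the questionnaire collects whole-year ages.
    """
    if ten_year_window <= 0:
        raise ValueError("ten_year_window must be positive")
    is_case = record.status == "case"
    onset = record.onset_age_years

    mtbi_pre = record.mtbi
    if (is_case and mtbi_pre is TriBool.YES and onset is not None
            and record.mtbi_first_age_years is not None
            and math.floor(record.mtbi_first_age_years) >= math.floor(onset)):
        mtbi_pre = TriBool.NO

    mtbi_10 = mtbi_pre
    if (is_case and mtbi_10 is TriBool.YES and onset is not None
            and record.mtbi_first_age_years is not None
            and math.floor(onset) - math.floor(record.mtbi_first_age_years)
            < ten_year_window):
        mtbi_10 = TriBool.NO

    pest = record.pesticide
    if (is_case and pest is TriBool.YES and onset is not None
            and record.pesticide_start_age_years is not None
            and math.floor(record.pesticide_start_age_years) >= math.floor(onset)):
        pest = TriBool.NO

    if pest is TriBool.YES:
        if (record.pesticide_start_age_years is not None
                and record.pesticide_end_age_years is not None):
            duration = (record.pesticide_end_age_years
                        - record.pesticide_start_age_years)
        else:
            duration = None
    elif pest is TriBool.NO:
        duration = 0.0
    else:
        duration = None

    fh = {"positive": True, "negative": False, "unknown": None}[record.family_history]
    return DerivedVariables(
        mtbi_precensored=mtbi_pre,
        mtbi_10yr=mtbi_10,
        pesticide_precensored=pest,
        pesticide_duration_years=duration,
        family_history_binary=fh,
    )


def _tb_float(v: TriBool) -> float:
    return {TriBool.YES: 1.0, TriBool.NO: 0.0, TriBool.UNKNOWN: np.nan}[v]


#: Variable names usable in models and complete-case filtering.
ANALYSIS_VARIABLES: tuple[str, ...] = (
    "status", "sex", "age", "onset_age", "family_history",
    "mtbi", "mtbi_10yr", "repeated_blows",
    "pesticide", "pesticide_duration", "agent_orange",
    "constipation", "rbd", "weight_loss",
)


def to_analysis_frame(
    records: Sequence[SubjectRecord], ten_year_window: float = 10.0
) -> pd.DataFrame:
    """Tabulate records as analysis variables (NaN marks unknown/absent).

    ``status`` is 1 for cases, 0 for controls; ``mtbi`` and ``pesticide``
    are the pre-onset-censored indicators; ``mtbi_10yr`` is the 10-year
    sensitivity recode.
    """
    rows = []
    for record in records:
        d = derive_variables(record, ten_year_window)
        rows.append({
            "subject_id": record.subject_id,
            "status": 1.0 if record.status == "case" else 0.0,
            "sex": record.sex if record.sex != "unknown" else None,
            "age": record.age_years if record.age_years is not None else np.nan,
            "onset_age": (record.onset_age_years
                          if record.onset_age_years is not None else np.nan),
            "family_history": (np.nan if d.family_history_binary is None
                               else float(d.family_history_binary)),
            "mtbi": _tb_float(d.mtbi_precensored),
            "mtbi_10yr": _tb_float(d.mtbi_10yr),
            "repeated_blows": _tb_float(record.repeated_blows),
            "pesticide": _tb_float(d.pesticide_precensored),
            "pesticide_duration": (d.pesticide_duration_years
                                   if d.pesticide_duration_years is not None
                                   else np.nan),
            "agent_orange": _tb_float(record.agent_orange),
            "constipation": _tb_float(record.constipation),
            "rbd": _tb_float(record.rbd),
            "weight_loss": _tb_float(record.weight_loss),
        })
    frame = pd.DataFrame(
        rows, columns=["subject_id"] + list(ANALYSIS_VARIABLES))
    return frame


def complete_case_subset(
    records: Sequence[SubjectRecord],
    variables: Iterable[str],
    ten_year_window: float = 10.0,
) -> list[SubjectRecord]:
    """Records with observed (non-unknown, non-absent) values for every
    listed analysis variable, in the original order."""
    variables = list(variables)
    for name in variables:
        if name not in ANALYSIS_VARIABLES:
            raise ValueError(
                f"unknown analysis variable {name!r}; "
                f"choose from {sorted(ANALYSIS_VARIABLES)}"
            )
    if not records:
        return []
    frame = to_analysis_frame(records, ten_year_window)
    keep = np.ones(len(records), dtype=bool)
    for name in variables:
        col = frame[name]
        keep &= col.notna().to_numpy()
    return [record for record, k in zip(records, keep) if k]
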