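"""Cohort file schemas, validation and row-to-record parsing.

The cohort CSV carries one row per woman (UTF-8, comma-separated, header
mandatory, empty string = missing).  Criterion columns use a triple
encoding: an integer delay in minutes, ``"done"`` (performed without an
applicable or recorded timing), ``"not_done"``, or ``""``.  Unit
characteristics live in a separate CSV keyed by ``unit_id``.  Unknown
columns pass through untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .scoring import (
    CareRecord,
    ClinicalContext,
    CriterionStatus,
    Criterion,
    UnscoreableContextError,
    classify_context,
    compute_score,
    classify_inadequate,
)
from .simulate import CRITERION_COLUMNS, UNTIMED

__all__ = [
    "COHORT_SCHEMA",
    "MANDATORY_COLUMNS",
    "RowError",
    "CohortValidationError",
    "read_cohort",
    "read_units",
    "write_cohort",
    "parse_criterion_cell",
    "care_record_from_row",
    "context_from_row",
    "score_dataframe",
]


@dataclass(frozen=True)
class ColumnSpec:
    semantic: str
    allowed: Optional[tuple] = None  # None -> free-form / numeric


_CRITERION_SPEC = ColumnSpec("criterion status: minutes | done | not_done | ''")

COHORT_SCHEMA: dict[str, ColumnSpec] = {
    "woman_id": ColumnSpec("identifier"),
    "unit_id": ColumnSpec("maternity unit identifier"),
    "delivery_mode": ColumnSpec("delivery mode", ("cesarean", "vaginal", "")),
    "uterine_atony": ColumnSpec("PPH cause is uterine atony", ("True", "False", "1", "0", "")),
    **{c: _CRITERION_SPEC for c in CRITERION_COLUMNS},
    "age_band": ColumnSpec("maternal age band", ("<25", "25-35", ">35", "")),
    "country_of_birth": ColumnSpec(
        "maternal country of birth",
        ("France", "other_europe", "north_africa", "sub_saharan_africa", "other", ""),
    ),
    "bmi_band": ColumnSpec("pre-pregnancy BMI band"),
    "parity_cesarean": ColumnSpec(
        "parity / previous cesarean",
        ("primiparous", "multiparous_no_cesarean", "multiparous_prior_cesarean", ""),
    ),
    "previous_pph": ColumnSpec("history of PPH", ("True", "False", "1", "0", "")),
    "multiple_pregnancy": ColumnSpec("multiple pregnancy", ("True", "False", "1", "0", "")),
    "pre_eclampsia": ColumnSpec("pre-eclampsia", ("True", "False", "1", "0", "")),
    "birth_weight_g": ColumnSpec("birth weight (g)"),
    "gestational_age_weeks": ColumnSpec("gestational age (weeks)"),
    "delivery_mode_detail": ColumnSpec("detailed delivery mode"),
}

MANDATORY_COLUMNS: tuple[str, ...] = (
    "woman_id",
    "unit_id",
    "delivery_mode",
    "uterine_atony",
    *CRITERION_COLUMNS,
)

UNITS_SCHEMA_COLUMNS = (
    "unit_id",
    "status",
    "level_of_care",
    "annual_deliveries_band",
    "obstetrician_24_7",
    "anesthesiologist_24_7",
)


@dataclass(frozen=True)
class RowError:
    row: int
    column: str
    message: str


class CohortValidationError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(str(e) for e in self.errors[:10]))


def _is_int_like(value: str) -> bool:
    try:
        return float(value) >= 0 and float(value) == int(float(value))
    except ValueError:
        return False


def validate_cohort(df: pd.DataFrame) -> list[RowError]:
    errors: list[RowError] = []
    for col in CRITERION_COLUMNS:
        for i, v in df[col].items():
            v = str(v)
            if v in ("done", "not_done", "") or _is_int_like(v):
                continue
            errors.append(RowError(int(i), col, f"unparseable criterion value {v!r}"))
    for col in ("delivery_mode", "uterine_atony"):
        allowed = COHORT_SCHEMA[col].allowed
        for i, v in df[col].items():
            if str(v) not in allowed:
                errors.append(RowError(int(i), col, f"value {v!r} not in {allowed}"))
    return errors


def read_cohort(path, strict: bool = False) -> tuple[pd.DataFrame, list[RowError]]:
    """Load and validate a cohort CSV; extra columns pass through.

    Missing mandatory columns are fatal.  Cell-level problems are returned
    as a list of :class:`RowError` (raised instead when ``strict``).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            [RowError(-1, c, "mandatory column missing") for c in missing]
        )
    errors = validate_cohort(df)
    if strict and errors:
        raise CohortValidationError(errors)
    return df, errors


def write_cohort(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.to_csv(path, index=False)


def read_units(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in UNITS_SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(
            [RowError(-1, c, "mandatory units column missing") for c in missing]
        )
    df["level_of_care"] = df["level_of_care"].astype(int)
    for c in ("obstetrician_24_7", "anesthesiologist_24_7"):
        df[c] = df[c].map(_parse_bool)
    return df


def _parse_bool(value) -> Optional[bool]:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    return None


def parse_criterion_cell(value, criterion: str) -> CriterionStatus:
    """Decode one criterion cell into a :class:`CriterionStatus`.

    ``"done"`` means performed: for untimed criteria that is complete
    evidence; for timed ones it means the timing went unrecorded.
    """
    s = str(value).strip()
    if s == "":
        return CriterionStatus.missing()
    if s == "not_done":
        return CriterionStatus.not_done()
    if s == "done":
        if criterion in UNTIMED:
            return CriterionStatus.done_untimed()
        return CriterionStatus.done_timing_unknown()
    if _is_int_like(s):
        return CriterionStatus.done_timed(float(s))
    raise ValueError(f"unparseable criterion value {value!r} for {criterion}")


def care_record_from_row(row) -> CareRecord:
    return CareRecord(
        **{c: parse_criterion_cell(row[c], c) for c in CRITERION_COLUMNS}
    )


def context_from_row(row) -> Optional[ClinicalContext]:
    """Clinical context of a cohort row, or ``None`` when unscoreable."""
    mode = str(row["delivery_mode"]).strip()
    atony = _parse_bool(row["uterine_atony"])
    try:
        return classify_context(mode if mode else None, atony)
    except UnscoreableContextError:
        return None


def score_dataframe(
    cohort: pd.DataFrame,
    quantile_level: float = 0.25,
    strict: bool = True,
    method: str = "linear",
    exclude_if_missing_criterion: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Score every row of a cohort frame and classify inadequate care.

    Returns a per-woman frame (earned/max points, ratio, percentage,
    unscoreable and inadequate flags) and a JSON-ready summary (threshold,
    counts).  Unscoreable rows carry NA points and are excluded from the
    percentile computation.
    """
    records = []
    for _, row in cohort.iterrows():
        ctx = context_from_row(row)
        if ctx is not None and exclude_if_missing_criterion:
            care = care_record_from_row(row)
            if any(care.status(c).state.value == "missing" for c in Criterion):
                ctx = None
        if ctx is None:
            records.append((row["woman_id"], None, None, None))
            continue
        qs = compute_score(care_record_from_row(row), ctx)
        records.append((row["woman_id"], qs.earned_points, qs.max_points, qs.ratio))
    out = pd.DataFrame(records, columns=["woman_id", "earned_points", "max_points", "ratio"])
    out["unscoreable"] = out["ratio"].isna()
    scoreable = out[~out["unscoreable"]]
    cls = classify_inadequate(
        scoreable["ratio"].to_numpy(), quantile_level=quantile_level,
        strict=strict, method=method,
    )
    out["inadequate"] = pd.Series(pd.NA, index=out.index, dtype="boolean")
    out.loc[scoreable.index, "inadequate"] = cls.flags
    out["percentage"] = 100.0 * out["ratio"]
    summary = {
        "n": int(len(out)),
        "n_scored": int((~out["unscoreable"]).sum()),
        "n_unscoreable": int(out["unscoreable"].sum()),
        "threshold": cls.threshold,
        "threshold_pct": 100.0 * cls.threshold,
        "quantile_level": quantile_level,
        "strict": strict,
        "quantile_method": method,
        "n_flagged": cls.n_flagged,
    }
    return out, summary


def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
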