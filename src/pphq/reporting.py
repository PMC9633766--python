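"""Cohort description tables: per-criterion compliance and characteristics.

Percentages follow the clinical-reporting convention: rounded
half-away-from-zero to one decimal (so 798/1104 prints as 72.3).  The
compliance table restricts each criterion's denominator to the women for
whom it applies — the two examination criteria to vaginal deliveries, the
second-line uterotonic rows to the atony / no-atony subgroups.
"""

from __future__ import annotations

import decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import CRITERION_COLUMNS  # noqa: F401  (schema shared with the generator)

__all__ = ["round_half_away", "pct", "compliance_table", "characteristics_table"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (5 rounds up in magnitude), fixed decimals."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> Optional[float]:
    """Percentage at the reporting precision; ``None`` on a zero denominator."""
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, ndigits)


# ----------------------------------------------------------------------


def _is_done(col: pd.Series) -> pd.Series:
    s = col.astype(str)
    return (s == "done") | s.str.fullmatch(r"\d+(\.\d+)?")


def _done_within(col: pd.Series, limit: float) -> pd.Series:
    s = col.astype(str)
    timed = s.str.fullmatch(r"\d+(\.\d+)?")
    delay = pd.to_numeric(s.where(timed), errors="coerce")
    return delay <= limit


def compliance_table(cohort: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-criterion compliance among scored women (Table-3-style report).

    One row per expected item of care: numerator, context-restricted
    denominator and the rounded percentage.
    """
    df = cohort.drop(columns=["unscoreable", "inadequate"], errors="ignore").merge(
        scores[["woman_id", "unscoreable"]], on="woman_id"
    )
    df = df[~df["unscoreable"]]
    vaginal = df["delivery_mode"].astype(str) == "vaginal"
    atony = df["uterine_atony"].astype(str).isin(("True", "1", "true"))
    rows = []

    def add(label: str, num_mask: pd.Series, den_mask: pd.Series) -> None:
        num = int((num_mask & den_mask).sum())
        den = int(den_mask.sum())
        rows.append({"item": label, "n": num, "N": den, "percent": pct(num, den)})

    everyone = pd.Series(True, index=df.index)
    add("prophylactic_uterotonic", _is_done(df["prophylactic_uterotonic"]), everyone)
    add("blood_loss_documented", _is_done(df["blood_loss_documented"]), everyone)
    add("first_line_any_delay", _is_done(df["first_line_uterotonic"]), everyone)
    add("first_line_le30", _done_within(df["first_line_uterotonic"], 30), everyone)
    add("hemoglobin_le60", _done_within(df["hemoglobin_measured"], 60), everyone)
    add("hemostasis_le60", _done_within(df["hemostasis_measured"], 60), everyone)
    add("manual_exam_le30_vaginal", _done_within(df["manual_uterine_exam"], 30), vaginal)
    add("cervix_exam_vaginal", _is_done(df["cervix_vagina_exam"]), vaginal)
    add(
        "second_line_any_delay_no_atony",
        _is_done(df["second_line_uterotonic"]),
        ~atony,
    )
    add(
        "second_line_le30_atony",
        _done_within(df["second_line_uterotonic"], 30),
        atony,
    )
    return pd.DataFrame(rows)


DEFAULT_CHARACTERISTICS = (
    "age_band",
    "country_of_birth",
    "parity_cesarean",
    "status",
    "level_of_care",
    "annual_deliveries_band",
    "obstetrician_24_7",
    "anesthesiologist_24_7",
)


def characteristics_table(
    cohort: pd.DataFrame,
    flags: pd.DataFrame,
    characteristics: Sequence[str] = DEFAULT_CHARACTERISTICS,
    logger=None,
) -> pd.DataFrame:
    """Cohort share (column %) and inadequate-care share (row %) per level.

    ``flags`` is the scores frame (``woman_id``, ``inadequate``,
    ``unscoreable``).  The overall row comes first; empty levels are
    omitted with a notice.
    """
    df = cohort.drop(columns=["unscoreable", "inadequate"], errors="ignore").merge(
        flags[["woman_id", "inadequate", "unscoreable"]], on="woman_id"
    )
    df = df[~df["unscoreable"]]
    n_total = len(df)
    n_flag_total = int(df["inadequate"].astype(bool).sum())
    rows = [
        {
            "characteristic": "all_women",
            "level": "",
            "n": n_total,
            "column_pct": pct(n_total, n_total),
            "n_inadequate": n_flag_total,
            "row_pct": pct(n_flag_total, n_total),
        }
    ]
    for char in characteristics:
        if char not in df.columns:
            continue
        col = df[char].astype(str)
        for level in sorted(col[col != ""].unique()):
            mask = col == level
            n = int(mask.sum())
            if n == 0:  # pragma: no cover - sorted uniques are non-empty
                if logger:
                    logger.info("level %s of %s empty; omitted", level, char)
                continue
            n_flag = int(df.loc[mask, "inadequate"].astype(bool).sum())
            rows.append(
                {
                    "characteristic": char,
                    "level": level,
                    "n": n,
                    "column_pct": pct(n, n_total),
                    "n_inadequate": n_flag,
                    "row_pct": pct(n_flag, n),
                }
            )
    return pd.DataFrame(rows)
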