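"""Maternity-unit determinants of inadequate PPH care.

The exposure of interest is the organisational environment of the maternity
unit: hospital status (public university / other public / private), level
of care (1-3, by on-site neonatal capability), annual delivery volume band,
and 24/24 on-site presence of an obstetrician and of an anesthesiologist.
The outcome is the binary inadequate-care flag from the quality score.

Because unit characteristics are strongly interrelated (in France small,
level-1 units are typically private; large level-3 units are typically
public university hospitals), each characteristic gets its own adjusted
model rather than one joint model, with collinearity screened through
variance inflation factors.  Every model is a random-intercept logistic
regression (the intercept varying by maternity unit) adjusted for the
individual confounders: the PPH risk-factor profile, maternal country of
birth, and parity / previous cesarean.  Analyses can be run on the whole
cohort or stratified by mode of delivery, and either on a single dataset
or across multiply-imputed datasets with Rubin pooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .glmm import FitResult, RandomInterceptLogit
from .imputation import pool_rubin

__all__ = [
    "WomanProfile",
    "UnitProfile",
    "CategorySpec",
    "UNIT_CHARACTERISTICS",
    "ADJUSTMENT_SPECS",
    "DEFAULT_ADJUSTMENT",
    "risk_profile",
    "risk_profile_series",
    "build_design",
    "vif",
    "run_model_suite",
]


# ----------------------------------------------------------------------
# typed profiles


@dataclass(frozen=True)
class WomanProfile:
    age_band: str  # "<25", "25-35", ">35"
    country_of_birth: Optional[str]  # France, other_europe, north_africa, sub_saharan_africa, other
    bmi_band: str
    parity_cesarean: str  # primiparous, multiparous_no_cesarean, multiparous_prior_cesarean
    previous_pph: bool
    multiple_pregnancy: bool
    pre_eclampsia: bool
    birth_weight_g: Optional[float]
    gestational_age_weeks: float
    delivery_mode_detail: str


@dataclass(frozen=True)
class UnitProfile:
    unit_id: str
    status: str  # public_university, public_non_university, private
    level_of_care: int  # 1, 2, 3
    annual_deliveries_band: str  # "<1000", "1000-2000", "2000-3500", ">=3500"
    obstetrician_24_7: bool
    anesthesiologist_24_7: bool


def risk_profile(w: WomanProfile) -> Optional[bool]:
    """At least one PPH risk factor: previous PPH, multiple pregnancy,
    pre-eclampsia, or birth weight >= 4000 g.

    Returns ``None`` (imputable missing) when the birth weight is unknown
    and no boolean factor is positive — the profile is then undetermined.
    """
    if w.previous_pph or w.multiple_pregnancy or w.pre_eclampsia:
        return True
    if w.birth_weight_g is None or (isinstance(w.birth_weight_g, float) and np.isnan(w.birth_weight_g)):
        return None
    return bool(w.birth_weight_g >= 4000)


def _as_bool(s: pd.Series) -> pd.Series:
    """Robust truthiness: handles bool dtype and 'True'/'1' strings from CSV."""
    if s.dtype == bool:
        return s
    return s.astype(str).str.strip().str.lower().isin(("true", "1"))


def risk_profile_series(df: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`risk_profile` over a cohort frame."""
    booleans = (
        _as_bool(df["previous_pph"])
        | _as_bool(df["multiple_pregnancy"])
        | _as_bool(df["pre_eclampsia"])
    )
    bw = pd.to_numeric(df["birth_weight_g"], errors="coerce")
    out = pd.Series(np.where(booleans, True, np.where(bw >= 4000, True, False)), index=df.index, dtype=object)
    out[~booleans & bw.isna()] = np.nan
    return out


# ----------------------------------------------------------------------
# design matrices


@dataclass(frozen=True)
class CategorySpec:
    """Dummy-coding recipe for one variable: reference level first."""

    column: str
    levels: tuple
    labels: tuple[str, ...]  # dummy column names, aligned with levels[1:]

    @property
    def reference(self):
        return self.levels[0]


UNIT_CHARACTERISTICS: dict[str, CategorySpec] = {
    "status": CategorySpec(
        "status",
        ("public_university", "public_non_university", "private"),
        ("status=public_non_university", "status=private"),
    ),
    "annual_deliveries": CategorySpec(
        "annual_deliveries_band",
        (">=3500", "2000-3500", "1000-2000", "<1000"),
        ("deliveries=2000-3500", "deliveries=1000-2000", "deliveries=<1000"),
    ),
    "level_of_care": CategorySpec(
        "level_of_care",
        (3, 2, 1),
        ("level_of_care=2", "level_of_care=1"),
    ),
    "obstetrician_24_7": CategorySpec(
        "obstetrician_24_7", (True, False), ("no_obstetrician_24_7",)
    ),
    "anesthesiologist_24_7": CategorySpec(
        "anesthesiologist_24_7", (True, False), ("no_anesthesiologist_24_7",)
    ),
}

ADJUSTMENT_SPECS: dict[str, CategorySpec] = {
    "risk_profile": CategorySpec("risk_profile", (False, True), ("risk_profile",)),
    "country_of_birth": CategorySpec(
        "country_of_birth",
        ("France", "other_europe", "north_africa", "sub_saharan_africa", "other"),
        (
            "country=other_europe",
            "country=north_africa",
            "country=sub_saharan_africa",
            "country=other",
        ),
    ),
    "parity_cesarean": CategorySpec(
        "parity_cesarean",
        ("primiparous", "multiparous_no_cesarean", "multiparous_prior_cesarean"),
        ("parity=multiparous_no_cesarean", "parity=multiparous_prior_cesarean"),
    ),
}

#: the individual-confounder set used by every adjusted model
DEFAULT_ADJUSTMENT: tuple[str, ...] = ("risk_profile", "country_of_birth", "parity_cesarean")


def _spec_for(name: str) -> CategorySpec:
    if name in UNIT_CHARACTERISTICS:
        return UNIT_CHARACTERISTICS[name]
    if name in ADJUSTMENT_SPECS:
        return ADJUSTMENT_SPECS[name]
    raise KeyError(f"unknown variable {name!r}")


def _dummies(df: pd.DataFrame, spec: CategorySpec) -> pd.DataFrame:
    observed = set(df[spec.column].dropna().unique())
    cols = {}
    if len(observed) < 2:
        warnings.warn(
            f"{spec.column}: single observed level {observed or '{}'}; no dummies emitted",
            stacklevel=3,
        )
        return pd.DataFrame(index=df.index)
    for level, label in zip(spec.levels[1:], spec.labels):
        if level not in observed:
            warnings.warn(f"{spec.column}: level {level!r} absent, column dropped", stacklevel=3)
            continue
        cols[label] = (df[spec.column] == level).astype(float)
    return pd.DataFrame(cols, index=df.index)


def build_design(
    records: pd.DataFrame,
    characteristic: str | Sequence[str],
    adjustment_set: Sequence[str] = DEFAULT_ADJUSTMENT,
    outcome: str = "inadequate",
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Outcome vector, dummy-coded design matrix and cluster ids.

    Reference levels (public university status, >= 3500 deliveries, level-3
    care, 24/24 presence of each specialist, born in France, primiparous,
    no risk factor) are absorbed into the intercept.  Rows with a missing
    value in any used variable are dropped.  Column order is deterministic:
    intercept, characteristic dummies, adjustment dummies.
    """
    chars = [characteristic] if isinstance(characteristic, str) else list(characteristic)
    specs = [_spec_for(c) for c in chars] + [_spec_for(a) for a in adjustment_set]
    used = [outcome, "unit_id"] + [s.column for s in specs]
    df = records[used]
    df = df.where(df.ne(""), np.nan).dropna()
    X = pd.concat([pd.DataFrame({"const": np.ones(len(df))}, index=df.index)]
                  + [_dummies(df, s) for s in specs], axis=1)
    y = df[outcome].astype(float).to_numpy()
    return y, X, df["unit_id"].to_numpy()


def vif(X: pd.DataFrame | np.ndarray) -> dict[str, float]:
    """Variance inflation factors, VIF_k = 1 / (1 - R^2_k).

    Each non-intercept column is regressed (with intercept) on all other
    non-intercept columns.  Perfect collinearity reports ``inf`` with a
    warning.
    """
    if isinstance(X, pd.DataFrame):
        names = [c for c in X.columns if c != "const"]
        M = X[names].to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(M.shape[1])]
    if M.shape[1] < 2:
        raise ValueError("VIF needs at least two non-intercept columns")
    out: dict[str, float] = {}
    n = len(M)
    ones = np.ones((n, 1))
    for k, name in enumerate(names):
        yk = M[:, k]
        Xk = np.c_[ones, np.delete(M, k, axis=1)]
        coef, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ coef
        ss_tot = np.sum((yk - yk.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"perfect collinearity for column {name!r}", stacklevel=2)
            out[name] = float("inf")
        else:
            out[name] = float(1.0 / (1.0 - r2))
    return out


# ----------------------------------------------------------------------
# model suites (Tables 4-5 layout)


def _fit_one(
    df: pd.DataFrame,
    characteristic: str | Sequence[str],
    adjustment: Sequence[str],
    n_quad: int,
) -> FitResult | None:
    y, X, cl = build_design(df, characteristic, adjustment)
    if X.shape[1] < 2 or len(np.unique(y)) < 2:
        return None
    try:
        return RandomInterceptLogit(y, X, cl, n_quad=n_quad).fit()
    except Exception as exc:  # keep the suite going on a pathological stratum
        warnings.warn(f"fit failed for {characteristic}: {exc}", stacklevel=2)
        return None


def _pooled_terms(fits: list[FitResult], terms: list[str]) -> dict[str, tuple[float, float, float]]:
    """Rubin-pool each term's log-odds across imputations; return OR scale."""
    out = {}
    for t in terms:
        present = [f for f in fits if t in f.coefficients]
        if len(present) != len(fits):
            continue
        pooled = pool_rubin(
            [f.coefficients[t] for f in present],
            [f.standard_errors[t] ** 2 for f in present],
        )
        out[t] = (
            float(np.exp(pooled.estimate)),
            float(np.exp(pooled.ci_low)),
            float(np.exp(pooled.ci_high)),
        )
    return out


def _result_rows(
    model_name: str,
    kind: str,
    chars: list[str],
    fits: list[FitResult],
) -> list[dict]:
    terms = sorted({t for f in fits for t in f.coefficients if t != "const"})
    if len(fits) == 1:
        f = fits[0]
        ors = {t: f.odds_ratios[t] for t in terms if t in f.odds_ratios}
    else:
        ors = _pooled_terms(fits, terms)
    converged = all(f.converged for f in fits)
    rows = []
    for c in chars:
        spec = _spec_for(c)
        rows.append(
            {
                "model": model_name,
                "kind": kind,
                "characteristic": c,
                "term": f"{spec.column}={spec.reference}",
                "OR": 1.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "reference": True,
                "converged": converged,
            }
        )
        for label in spec.labels:
            if label not in ors:
                continue
            point, lo, hi = ors[label]
            rows.append(
                {
                    "model": model_name,
                    "kind": kind,
                    "characteristic": c,
                    "term": label,
                    "OR": point,
                    "ci_low": lo,
                    "ci_high": hi,
                    "reference": False,
                    "converged": converged,
                }
            )
    return rows


def run_model_suite(
    cohort: pd.DataFrame,
    stratum: str = "all",
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
    imputations: Sequence[pd.DataFrame] | None = None,
    n_quad: int = 15,
    include_crude: bool = True,
) -> pd.DataFrame:
    """Crude and adjusted ORs for every unit characteristic in one stratum.

    One adjusted model per characteristic (models 1-5); the vaginal stratum
    additionally gets the combined status + delivery-volume model (model 6).
    Crude models contain the characteristic alone, still with the unit
    random intercept.  With ``imputations`` the same models are fitted on
    each completed dataset and Rubin-pooled.  Models that fail to converge
    are reported with ``converged=False``; the suite always completes.
    """
    if stratum not in {"all", "vaginal", "cesarean"}:
        raise ValueError(f"unknown stratum {stratum!r}")

    def _strat(df: pd.DataFrame) -> pd.DataFrame:
        return df if stratum == "all" else df[df["delivery_mode"] == stratum]

    datasets = [_strat(cohort)] if imputations is None else [_strat(d) for d in imputations]
    model_chars: dict[str, list[str]] = {
        f"model_{i}": [c] for i, c in enumerate(UNIT_CHARACTERISTICS, start=1)
    }
    if stratum == "vaginal":
        model_chars["model_6"] = ["status", "annual_deliveries"]
    rows: list[dict] = []
    for name, chars in model_chars.items():
        if include_crude and len(chars) == 1:
            fits = [f for f in (_fit_one(d, chars[0], (), n_quad) for d in datasets) if f]
            if fits:
                rows += _result_rows(name, "crude", chars, fits)
        fits = [f for f in (_fit_one(d, chars, adjustment, n_quad) for d in datasets) if f]
        if fits:
            rows += _result_rows(name, "adjusted", chars, fits)
        else:
            for c in chars:
                rows.append(
                    {
                        "model": name,
                        "kind": "adjusted",
                        "characteristic": c,
                        "term": None,
                        "OR": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "reference": False,
                        "converged": False,
                    }
                )
    return pd.DataFrame(rows)
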