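"""Multiple imputation by chained equations (MICE) and Rubin pooling.

Missing covariate cells — in this cohort principally "country of birth",
missing for about one woman in ten — are filled in m times (default 12) by
iteratively drawing each incomplete variable from a conditional model given
all other variables.  Conditional models are type-appropriate: logistic for
binary variables, multinomial logistic for unordered categoricals, and
predictive mean matching (PMM) for numeric ones.  Parameter uncertainty is
propagated by fitting each conditional model on a bootstrap resample of the
complete rows before drawing, the standard approximation to drawing from
the parameter posterior.

Analyses run once per completed dataset and are combined with Rubin's
rules: the pooled estimate is the mean of the per-imputation estimates, and
the pooled variance adds the average within-imputation variance W and the
between-imputation variance B as T = W + (1 + 1/m) B, with Student-t
intervals on (m - 1)(1 + W / ((1 + 1/m) B))^2 degrees of freedom.  Pooling
of odds ratios happens on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputationConfig", "PooledEstimate", "mice_impute", "pool_rubin", "pool_fit_results"]


@dataclass
class ImputationConfig:
    m: int = 12
    n_cycles: int = 10
    seed: int = 0
    variable_models: dict[str, str] = field(default_factory=dict)
    pmm_donors: int = 5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m >= 2 required for Rubin pooling")
        for v, kind in self.variable_models.items():
            if kind not in {"logistic", "multinomial", "pmm"}:
                raise ValueError(f"unknown model {kind!r} for variable {v!r}")


@dataclass
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    m: int


def pool_rubin(estimates: Sequence[float], variances: Sequence[float]) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules.

    With identical estimates the between-imputation variance is zero; the
    degrees of freedom are then infinite by convention and the interval uses
    the normal quantile.
    """
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = len(q)
    if m < 2:
        raise ValueError("m >= 2 required")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    qbar = float(q.mean())
    within = float(v.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between == 0.0:
        df = float("inf")
        tcrit = stats.norm.ppf(0.975)
    else:
        r = (1.0 + 1.0 / m) * between
        df = (m - 1) * (1.0 + within / r) ** 2
        tcrit = stats.t.ppf(0.975, df)
    half = tcrit * np.sqrt(total)
    return PooledEstimate(
        estimate=qbar,
        within_var=within,
        between_var=between,
        total_var=total,
        df=df,
        ci_low=qbar - half,
        ci_high=qbar + half,
        m=m,
    )


def pool_fit_results(fits, term: str) -> PooledEstimate:
    """Rubin-pool one coefficient (log-odds scale) across per-imputation fits."""
    est = [f.coefficients[term] for f in fits]
    var = [f.standard_errors[term] ** 2 for f in fits]
    return pool_rubin(est, var)


# ----------------------------------------------------------------------
# chained-equations engine


def _infer_model(series: pd.Series) -> str:
    vals = series.dropna().unique()
    if series.dtype == bool or len(vals) == 2:
        return "logistic"
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return "multinomial"
    return "pmm"


def _encode_predictors(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """One-hot encode everything except the target variable."""
    preds = df.drop(columns=[exclude])
    enc = pd.get_dummies(preds, dummy_na=False, drop_first=True)
    X = enc.to_numpy(dtype=float)
    return np.c_[np.ones(len(X)), X]


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray, classes: np.ndarray):
    cum = np.cumsum(probs, axis=1)
    r = rng.random(len(probs))[:, None]
    idx = (r > cum).sum(axis=1)
    return classes[idx]


def _impute_variable(
    df: pd.DataFrame,
    var: str,
    kind: str,
    miss_mask: np.ndarray,
    rng: np.random.Generator,
    pmm_donors: int,
) -> None:
    """One Gibbs update of `var` in place (df currently fully filled)."""
    from sklearn.linear_model import LogisticRegression

    X = _encode_predictors(df, exclude=var)
    obs = ~miss_mask
    X_obs, X_mis = X[obs], X[miss_mask]
    y_obs = df.loc[obs, var].to_numpy()
    # bootstrap the fitting sample: approximate parameter draw
    boot = rng.integers(0, len(X_obs), len(X_obs))
    Xb, yb = X_obs[boot], y_obs[boot]
    if len(np.unique(yb)) < 2:
        df.loc[miss_mask, var] = yb[0]
        return
    if kind in ("logistic", "multinomial"):
        # fit on stringified labels (object columns confuse the classifier),
        # then map draws back to the original values
        back = {str(v): v for v in pd.unique(y_obs)}
        model = LogisticRegression(max_iter=500, C=1e4)
        model.fit(Xb, yb.astype(str))
        probs = model.predict_proba(X_mis)
        drawn_str = _draw_categorical(rng, probs, model.classes_)
        df.loc[miss_mask, var] = np.array([back[s] for s in drawn_str], dtype=object)
    elif kind == "pmm":
        yb_f = yb.astype(float)
        coef, *_ = np.linalg.lstsq(Xb, yb_f, rcond=None)
        pred_obs = X_obs @ coef
        pred_mis = X_mis @ coef
        # match each missing cell to one of its k nearest observed donors
        order = np.argsort(pred_obs)
        pos = np.searchsorted(pred_obs[order], pred_mis)
        drawn = np.empty(len(pred_mis))
        k = pmm_donors
        for i, p in enumerate(pos):
            lo = max(0, p - k)
            hi = min(len(order), p + k)
            donors = order[lo:hi]
            drawn[i] = y_obs[rng.choice(donors)]
        df.loc[miss_mask, var] = drawn
    else:  # pragma: no cover
        raise ValueError(kind)


def mice_impute(dataset: pd.DataFrame, config: ImputationConfig) -> list[pd.DataFrame]:
    """Produce ``config.m`` completed copies of ``dataset``.

    Empty strings are treated as missing.  Observed cells are identical
    across (and to) the input; only missing cells vary between imputations.
    Fully deterministic for a fixed ``config.seed``.
    """
    df0 = dataset.where(dataset.ne(""), np.nan).copy()
    miss = {c: df0[c].isna().to_numpy() for c in df0.columns if df0[c].isna().any()}
    for var, mask in miss.items():
        if mask.all():
            raise ValueError(f"variable {var!r} is missing for every record")
    if not miss:
        return [dataset.copy() for _ in range(config.m)]
    kinds = {
        var: config.variable_models.get(var, _infer_model(df0[var])) for var in miss
    }
    rng = np.random.default_rng(config.seed)
    completed: list[pd.DataFrame] = []
    for _ in range(config.m):
        df = df0.copy()
        # initial fill: random draws from the observed margin
        for var, mask in miss.items():
            pool = df.loc[~mask, var].to_numpy()
            df.loc[mask, var] = rng.choice(pool, size=int(mask.sum()))
        for _cycle in range(config.n_cycles):
            for var, mask in miss.items():
                _impute_variable(df, var, kinds[var], mask, rng, config.pmm_donors)
        completed.append(df)
    return completed


def missingness_report(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-variable missingness counts and rates (empty string = missing)."""
    df = dataset.where(dataset.ne(""), np.nan)
    n = len(df)
    rows = [
        {"variable": c, "n_missing": int(df[c].isna().sum()), "rate": df[c].isna().mean()}
        for c in df.columns
        if df[c].isna().any()
    ]
    return pd.DataFrame(rows, columns=["variable", "n_missing", "rate"])
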