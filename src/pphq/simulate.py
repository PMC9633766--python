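"""Synthetic clustered cohorts of severe postpartum hemorrhage.

Generates maternity units, women nested within them, and criterion-level
care events, so the scoring and determinant-analysis machinery can be
exercised end to end without any external data.  Defaults emulate the
published margins of a French population-based severe-PPH cohort:
119 units, roughly 1100 women, 35.7% cesarean deliveries, 69.8% uterine
atony, per-criterion compliance near the printed levels (e.g. ~72% of
first-line uterotonics within 30 minutes), and missing-at-random country
of birth at a 9.6% rate.

The generative model for care is a shared-latent-quality model: each unit
draws one latent effect u_j ~ Normal(0, sigma_u^2); each criterion for each
woman is performed with probability logit^-1(logit(base) + effects + u_j),
where `effects` are configurable log-odds shifts attached to unit
characteristics (all zero by default).  Delays are log-normal in minutes.
Sharing u_j across criteria induces realistic within-unit correlation of
the inadequate-care outcome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "GeneratorConfig",
    "UnitTableCell",
    "SimulatedCohort",
    "default_unit_table",
    "generate_units",
    "generate_women",
    "generate_care",
    "generate_cohort",
    "CRITERION_COLUMNS",
]

CRITERION_COLUMNS = (
    "prophylactic_uterotonic",
    "blood_loss_documented",
    "first_line_uterotonic",
    "hemoglobin_measured",
    "hemostasis_measured",
    "manual_uterine_exam",
    "cervix_vagina_exam",
    "second_line_uterotonic",
)

UNTIMED = {"prophylactic_uterotonic", "blood_loss_documented", "cervix_vagina_exam"}

VOLUME_BANDS = ("<1000", "1000-2000", "2000-3500", ">=3500")


class UnitTableCell(NamedTuple):
    """One cell of the joint unit-characteristic distribution."""

    prob: float
    status: str
    level_of_care: int
    annual_deliveries_band: str
    obstetrician_24_7: bool
    anesthesiologist_24_7: bool


# Per-volume-band conditional distributions, chosen so that the *women-level*
# margins (units weighted by their delivery volume) land near the cohort
# description: status 40/45/15% (university/other public/private), level of
# care 35/44/21% (3/2/1), volume 18/43/26/13%, 24/24 obstetrician 78%,
# 24/24 anesthesiologist 91%.
_BAND_PROB = {"<1000": 0.30, "1000-2000": 0.33, "2000-3500": 0.29, ">=3500": 0.08}
_BAND_WOMEN_MEAN = {"<1000": 4.2, "1000-2000": 7.3, "2000-3500": 13.6, ">=3500": 20.9}
_STATUS_GIVEN_BAND = {
    "<1000": {"public_university": 0.10, "public_non_university": 0.55, "private": 0.35},
    "1000-2000": {"public_university": 0.15, "public_non_university": 0.63, "private": 0.22},
    "2000-3500": {"public_university": 0.45, "public_non_university": 0.43, "private": 0.12},
    ">=3500": {"public_university": 0.85, "public_non_university": 0.15, "private": 0.0},
}
_LEVEL_GIVEN_BAND = {
    "<1000": {1: 0.78, 2: 0.22, 3: 0.0},
    "1000-2000": {1: 0.35, 2: 0.60, 3: 0.05},
    "2000-3500": {1: 0.05, 2: 0.52, 3: 0.43},
    ">=3500": {1: 0.0, 2: 0.20, 3: 0.80},
}
_OBST_GIVEN_BAND = {"<1000": 0.30, "1000-2000": 0.70, "2000-3500": 0.90, ">=3500": 1.0}
_ANESTH_GIVEN_BAND = {"<1000": 0.55, "1000-2000": 0.90, "2000-3500": 1.0, ">=3500": 1.0}


def default_unit_table() -> tuple[UnitTableCell, ...]:
    """Joint table over status x level x volume x staffing (sums to 1)."""
    cells = []
    for band, p_band in _BAND_PROB.items():
        for status, p_s in _STATUS_GIVEN_BAND[band].items():
            for level, p_l in _LEVEL_GIVEN_BAND[band].items():
                for obst in (True, False):
                    p_o = _OBST_GIVEN_BAND[band] if obst else 1 - _OBST_GIVEN_BAND[band]
                    for anesth in (True, False):
                        p_a = (
                            _ANESTH_GIVEN_BAND[band]
                            if anesth
                            else 1 - _ANESTH_GIVEN_BAND[band]
                        )
                        p = p_band * p_s * p_l * p_o * p_a
                        if p > 0:
                            cells.append(UnitTableCell(p, status, level, band, obst, anesth))
    return tuple(cells)


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_units: int = 119
    women_per_unit_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(_BAND_WOMEN_MEAN)
    )
    women_dispersion: Optional[float] = None  # None -> Poisson; else NegBin size
    unit_table: Sequence[UnitTableCell] = field(default_factory=default_unit_table)
    sigma_u: float = 0.5
    criterion_base_compliance: Mapping[str, float] = field(
        default_factory=lambda: {
            "prophylactic_uterotonic": 0.917,
            "blood_loss_documented": 0.849,
            "first_line_uterotonic": 0.889,
            "hemoglobin_measured": 0.84,
            "hemostasis_measured": 0.55,
            "manual_uterine_exam": 0.80,
            "cervix_vagina_exam": 0.63,
            "second_line_uterotonic": 0.62,  # atony contexts
            "second_line_uterotonic_no_atony": 0.357,
        }
    )
    timing_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {  # (median minutes, log-scale sd)
            "first_line_uterotonic": (16.0, 0.70),
            "hemoglobin_measured": (30.0, 0.65),
            "hemostasis_measured": (32.0, 0.65),
            "manual_uterine_exam": (13.5, 0.60),
            "second_line_uterotonic": (15.0, 0.70),
        }
    )
    effect_map: Mapping[tuple[str, object], float] = field(default_factory=dict)
    atony_probability: float = 0.698
    cesarean_probability: float = 0.357
    missing_country_rate: float = 0.096
    missing_context_rate: float = 0.0
    timing_unknown_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        probs = [c.prob for c in self.unit_table]
        if abs(sum(probs) - 1.0) > 1e-8:
            raise ValueError("unit table probabilities must sum to 1")
        for p in list(self.criterion_base_compliance.values()) + [
            self.atony_probability,
            self.cesarean_probability,
            self.missing_country_rate,
            self.missing_context_rate,
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")


class SimulatedCohort(NamedTuple):
    units: pd.DataFrame
    cohort: pd.DataFrame  # women covariates + care columns, one row per woman
    mechanism: pd.DataFrame  # per-row MAR missingness probability
    truth: dict  # generating parameters, for recovery tests


def generate_units(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ``n_units`` profiles from the joint characteristic table."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    cells = list(config.unit_table)
    if len(cells) == 1:
        import warnings

        warnings.warn("degenerate unit table: a single cell", stacklevel=2)
    probs = np.array([c.prob for c in cells])
    idx = rng.choice(len(cells), size=config.n_units, p=probs / probs.sum())
    rows = []
    for j, i in enumerate(idx):
        c = cells[i]
        rows.append(
            {
                "unit_id": f"U{j:03d}",
                "status": c.status,
                "level_of_care": c.level_of_care,
                "annual_deliveries_band": c.annual_deliveries_band,
                "obstetrician_24_7": c.obstetrician_24_7,
                "anesthesiologist_24_7": c.anesthesiologist_24_7,
            }
        )
    return pd.DataFrame(rows)


_AGE_BANDS = ("<25", "25-35", ">35")
_AGE_PROBS = (0.149, 0.637, 0.214)
_COUNTRIES = ("France", "other_europe", "north_africa", "sub_saharan_africa", "other")
_COUNTRY_PROBS = (0.709, 0.034, 0.096, 0.093, 0.068)
_BMI_BANDS = ("<18.5", "18.5-25", "25-30", ">=30")
_BMI_PROBS = (0.072, 0.603, 0.197, 0.128)
_PARITY = ("primiparous", "multiparous_no_cesarean", "multiparous_prior_cesarean")
_PARITY_PROBS = (0.501, 0.360, 0.139)


def generate_women(
    units: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Women nested in units, with covariates and MAR-missing country.

    Cluster sizes are Poisson (or negative binomial when a dispersion is
    configured) with a volume-band-specific mean, so larger units contribute
    more women, as in the source population.  Country of birth is blanked
    missing-at-random with probability depending on observed covariates
    (private unit, maternal age < 25); the mechanism's per-row probability
    is returned so the MAR assumption is checkable by construction.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    for _, u in units.iterrows():
        mean = config.women_per_unit_mean[u["annual_deliveries_band"]]
        if config.women_dispersion is None:
            n_w = rng.poisson(mean)
        else:
            size = config.women_dispersion
            n_w = rng.negative_binomial(size, size / (size + mean))
        for _ in range(n_w):
            rows.append({"unit_id": u["unit_id"]})
    women = pd.DataFrame(rows)
    n = len(women)
    women.insert(0, "woman_id", [f"W{i:05d}" for i in range(n)])

    cesarean = rng.random(n) < config.cesarean_probability
    women["delivery_mode"] = np.where(cesarean, "cesarean", "vaginal")
    detail = np.empty(n, dtype=object)
    # conditional splits of the printed mode-of-delivery mix
    detail[cesarean] = rng.choice(
        ["antepartum_cesarean", "intrapartum_cesarean"], size=int(cesarean.sum()), p=[0.51, 0.49]
    )
    detail[~cesarean] = rng.choice(
        ["spontaneous_vaginal", "operative_vaginal"], size=int((~cesarean).sum()), p=[0.707, 0.293]
    )
    women["delivery_mode_detail"] = detail
    atony = rng.random(n) < config.atony_probability
    women["uterine_atony"] = atony
    women["age_band"] = rng.choice(_AGE_BANDS, size=n, p=_AGE_PROBS)
    women["country_of_birth"] = rng.choice(_COUNTRIES, size=n, p=_COUNTRY_PROBS)
    women["bmi_band"] = rng.choice(_BMI_BANDS, size=n, p=_BMI_PROBS)
    women["parity_cesarean"] = rng.choice(_PARITY, size=n, p=_PARITY_PROBS)
    women["previous_pph"] = rng.random(n) < 0.063
    women["multiple_pregnancy"] = rng.random(n) < 0.103
    women["pre_eclampsia"] = rng.random(n) < 0.045
    women["birth_weight_g"] = np.round(np.clip(rng.normal(3400, 560, n), 500, 6000))
    women["gestational_age_weeks"] = np.round(np.clip(rng.normal(39.2, 1.9, n), 24, 43), 1)

    # MAR missingness for country of birth: depends on observed covariates
    women = women.merge(units[["unit_id", "status"]], on="unit_id", how="left")
    shift = 0.8 * (women["status"] == "private").to_numpy() + 0.6 * (
        women["age_band"] == "<25"
    ).to_numpy()
    p_miss = _calibrated_mar_probs(shift, config.missing_country_rate)
    women = women.drop(columns=["status"])
    blank = rng.random(n) < p_miss
    women.loc[blank, "country_of_birth"] = ""
    mechanism = pd.DataFrame(
        {"woman_id": women["woman_id"], "p_missing_country": p_miss}
    )

    if config.missing_context_rate > 0:
        ctx_blank = rng.random(n) < config.missing_context_rate
        women["uterine_atony"] = women["uterine_atony"].astype(object)
        women.loc[ctx_blank, "uterine_atony"] = ""
    return women, mechanism


def _calibrated_mar_probs(shift: np.ndarray, target_rate: float) -> np.ndarray:
    """Choose the MAR intercept so the mean missingness hits the target."""
    if target_rate <= 0:
        return np.zeros_like(shift)
    lo, hi = -15.0, 15.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + shift).mean() < target_rate:
            lo = mid
        else:
            hi = mid
    return expit(0.5 * (lo + hi) + shift)


def generate_care(
    women: pd.DataFrame,
    units: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-woman criterion columns in the cohort CSV encoding.

    Each cell holds an integer delay in minutes (timed criteria performed
    with a recorded time), ``"done"`` (performed, no timing applicable or
    recorded), ``"not_done"``, or ``""`` (missing).  Returns the care frame
    and a per-unit frame of the latent quality draws (truth for tests).
    """
    rng = rng or np.random.default_rng(config.seed)
    units = units.set_index("unit_id")
    u_draws = pd.Series(
        rng.normal(0.0, config.sigma_u, len(units)), index=units.index, name="u"
    )
    shifts = pd.Series(0.0, index=units.index, name="effect_shift")
    for (column, level), eff in config.effect_map.items():
        shifts = shifts + eff * (units[column] == level).astype(float)
    shifts.name = "effect_shift"
    per_unit = units.join(u_draws).join(shifts).reset_index()

    n = len(women)
    unit_u = women["unit_id"].map(u_draws).to_numpy()
    unit_shift = women["unit_id"].map(shifts).to_numpy()
    atony = women["uterine_atony"].map(lambda a: bool(a) if a != "" else False).to_numpy()

    care = pd.DataFrame(index=women.index)
    for crit in CRITERION_COLUMNS:
        if crit == "second_line_uterotonic":
            base = np.where(
                atony,
                config.criterion_base_compliance["second_line_uterotonic"],
                config.criterion_base_compliance["second_line_uterotonic_no_atony"],
            )
        else:
            base = np.full(n, config.criterion_base_compliance[crit])
        p_done = expit(logit(base) + unit_shift + unit_u)
        done = rng.random(n) < p_done
        col = np.where(done, "done", "not_done").astype(object)
        if crit not in UNTIMED:
            median, sd = config.timing_distributions[crit]
            delays = np.round(rng.lognormal(np.log(median), sd, n)).astype(int)
            timed = done & (rng.random(n) >= config.timing_unknown_rate)
            col[timed] = delays[timed].astype(str)
        care[crit] = col
    return care, per_unit


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> SimulatedCohort:
    """Run the full generator: units -> women -> care, with truth attached."""
    config = config or GeneratorConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    units = generate_units(config, rng)
    women, mechanism = generate_women(units, config, rng)
    care, per_unit = generate_care(women, units, config, rng)
    cohort = pd.concat([women, care], axis=1)
    truth = {
        "config": config,
        "unit_effects": per_unit,
        "n_units": len(units),
        "n_women": len(women),
    }
    return SimulatedCohort(units=units, cohort=cohort, mechanism=mechanism, truth=truth)
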