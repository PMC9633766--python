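"""Case selection for the severe-PPH cohort.

Severe postpartum hemorrhage is defined by at least one positive severity
indicator: major bleeding (blood loss >= 1500 mL, transfusion of >= 4 red
blood cell units, or a surgical procedure / arterial embolization for
hemostasis), acute hematologic dysfunction (hemoglobin nadir <= 7 g/dL,
platelets <= 50,000 /mm3, disseminated intravascular coagulation), any organ
failure, admission to an intensive care unit, or maternal death.  All
thresholds are inclusive; a missing indicator never qualifies a case — the
definition requires positive evidence.

Cases whose management is etiology-specific and outside first-line PPH
guidelines (surgical wound without atony, abnormally invasive placenta,
uterine rupture, amniotic fluid embolism, vaginal thrombus without atony,
uterine inversion, secondary PPH, PPH at home) are excluded after severity
selection; the exclusion flags may overlap, so exclusion is a union.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Optional

__all__ = [
    "SeverityIndicators",
    "EtiologyFlags",
    "CaseRecord",
    "FlowAccount",
    "is_severe_pph",
    "is_excluded",
    "build_flow",
]


@dataclass(frozen=True)
class SeverityIndicators:
    blood_loss_ml: Optional[float] = None
    rbc_units_transfused: Optional[int] = None
    surgical_procedure_or_embolization: bool = False
    hemoglobin_nadir_g_dl: Optional[float] = None
    platelets_per_mm3: Optional[int] = None
    dic: bool = False
    organ_failure: bool = False
    icu_admission: bool = False
    maternal_death: bool = False
    near_miss: bool = False  # WHO label, carried through untouched


@dataclass(frozen=True)
class EtiologyFlags:
    surgical_wound_without_atony: bool = False
    abnormal_placental_insertion: bool = False
    uterine_rupture: bool = False
    amniotic_fluid_embolism: bool = False
    vaginal_thrombus_without_atony: bool = False
    uterine_inversion: bool = False
    secondary_pph: bool = False
    pph_at_home: bool = False

    def active(self) -> tuple[str, ...]:
        return tuple(f.name for f in fields(self) if getattr(self, f.name))


@dataclass(frozen=True)
class CaseRecord:
    """One candidate case: severity evidence, etiology flags, scoreability."""

    severity: SeverityIndicators
    etiology: EtiologyFlags
    scoreable: bool = True


@dataclass
class FlowAccount:
    """Cohort flow accounting: input -> severe -> eligible -> scored."""

    n_input: int
    n_severe: int
    n_excluded_by_flag: dict[str, int]
    n_eligible: int
    n_unscoreable: int
    n_final: int

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_severe": self.n_severe,
            "n_excluded_by_flag": dict(self.n_excluded_by_flag),
            "n_eligible": self.n_eligible,
            "n_unscoreable": self.n_unscoreable,
            "n_final": self.n_final,
        }


def is_severe_pph(ind: SeverityIndicators) -> bool:
    """True iff any severity indicator qualifies (inclusive thresholds)."""
    return (
        (ind.blood_loss_ml is not None and ind.blood_loss_ml >= 1500)
        or (ind.rbc_units_transfused is not None and ind.rbc_units_transfused >= 4)
        or ind.surgical_procedure_or_embolization
        or (ind.hemoglobin_nadir_g_dl is not None and ind.hemoglobin_nadir_g_dl <= 7.0)
        or (ind.platelets_per_mm3 is not None and ind.platelets_per_mm3 <= 50_000)
        or ind.dic
        or ind.organ_failure
        or ind.icu_admission
        or ind.maternal_death
    )


def is_excluded(flags: EtiologyFlags) -> bool:
    """True iff any etiology exclusion flag is set (union semantics)."""
    return bool(flags.active())


def build_flow(records: Iterable[CaseRecord]) -> FlowAccount:
    """Apply severity inclusion then etiology exclusion, counting each step.

    Per-flag exclusion tallies count every active flag, so their sum can
    exceed the number of excluded women (flags are not mutually exclusive).
    """
    flag_names = [f.name for f in fields(EtiologyFlags)]
    per_flag = {name: 0 for name in flag_names}
    n_input = n_severe = n_eligible = n_unscoreable = 0
    for rec in records:
        n_input += 1
        if not is_severe_pph(rec.severity):
            continue
        n_severe += 1
        active = rec.etiology.active()
        for name in active:
            per_flag[name] += 1
        if active:
            continue
        n_eligible += 1
        if not rec.scoreable:
            n_unscoreable += 1
    return FlowAccount(
        n_input=n_input,
        n_severe=n_severe,
        n_excluded_by_flag=per_flag,
        n_eligible=n_eligible,
        n_unscoreable=n_unscoreable,
        n_final=n_eligible - n_unscoreable,
    )
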