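"""Quality-of-care scoring for severe postpartum hemorrhage (PPH).

The score combines eight expert-weighted criteria of PPH prevention and
first-line management into a single per-woman figure: the ratio of points
earned over the maximum attainable in the woman's clinical context.  The
context is the cell of a 2x2 grid — delivery mode (cesarean / vaginal)
crossed with PPH cause (uterine atony / other) — because two criteria apply
only after vaginal delivery and the second-line uterotonic criterion is
weighted differently when the uterus is atonic.

Criteria are weighted major (2 points) or minor (1 point).  Timed criteria
earn full credit only when performed within their delay cut-off (30 or
60 minutes, inclusive); a procedure not noted in the chart counts as not
done.  A woman's score of, say, 10/15 means two-thirds of the management
items expected in her situation were delivered adequately.

"Inadequate care" is a cohort-level binary flag: a score strictly below the
25th percentile of the score distribution in the study population.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DeliveryMode",
    "Criterion",
    "State",
    "ClinicalContext",
    "CriterionStatus",
    "CareRecord",
    "QualityScore",
    "InadequateCareClassification",
    "UnscoreableContextError",
    "classify_context",
    "evaluate_criterion",
    "compute_score",
    "score_cohort",
    "classify_inadequate",
    "CONTEXT_MAX_POINTS",
    "NOT_APPLICABLE",
]


class DeliveryMode(str, enum.Enum):
    CESAREAN = "cesarean"
    VAGINAL = "vaginal"


class Criterion(str, enum.Enum):
    """The eight care criteria, in grid order."""

    PROPHYLACTIC_UTEROTONIC = "prophylactic_uterotonic"
    BLOOD_LOSS_DOCUMENTED = "blood_loss_documented"
    FIRST_LINE_UTEROTONIC = "first_line_uterotonic"
    HEMOGLOBIN_MEASURED = "hemoglobin_measured"
    HEMOSTASIS_MEASURED = "hemostasis_measured"
    MANUAL_UTERINE_EXAM = "manual_uterine_exam"
    CERVIX_VAGINA_EXAM = "cervix_vagina_exam"
    SECOND_LINE_UTEROTONIC = "second_line_uterotonic"


#: Criteria whose credit depends on a delay (minutes from the anchor event).
TIMED_CRITERIA = frozenset(
    {
        Criterion.FIRST_LINE_UTEROTONIC,
        Criterion.HEMOGLOBIN_MEASURED,
        Criterion.HEMOSTASIS_MEASURED,
        Criterion.MANUAL_UTERINE_EXAM,
        Criterion.SECOND_LINE_UTEROTONIC,
    }
)

#: Criteria scored only after vaginal delivery (not applicable in cesarean).
VAGINAL_ONLY_CRITERIA = frozenset(
    {Criterion.MANUAL_UTERINE_EXAM, Criterion.CERVIX_VAGINA_EXAM}
)

#: Delay cut-off in minutes for each timed criterion (inclusive).
TIME_LIMITS_MIN = {
    Criterion.FIRST_LINE_UTEROTONIC: 30.0,
    Criterion.HEMOGLOBIN_MEASURED: 60.0,
    Criterion.HEMOSTASIS_MEASURED: 60.0,
    Criterion.MANUAL_UTERINE_EXAM: 30.0,
    Criterion.SECOND_LINE_UTEROTONIC: 30.0,
}


class State(str, enum.Enum):
    DONE_TIMED = "done_timed"
    DONE_TIMING_UNKNOWN = "done_timing_unknown"
    DONE_UNTIMED = "done_untimed"
    NOT_DONE = "not_done"
    MISSING = "missing"


_DONE_STATES = frozenset({State.DONE_TIMED, State.DONE_TIMING_UNKNOWN, State.DONE_UNTIMED})


class UnscoreableContextError(ValueError):
    """Raised when the clinical context cannot be established for a record."""


@dataclass(frozen=True)
class ClinicalContext:
    """One of the four cells of the scoring grid."""

    delivery_mode: DeliveryMode
    uterine_atony: bool

    @property
    def max_points(self) -> int:
        return CONTEXT_MAX_POINTS[(self.delivery_mode, self.uterine_atony)]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        atony = "atony" if self.uterine_atony else "no-atony"
        return f"{self.delivery_mode.value}/{atony}"


CONTEXT_MAX_POINTS: Mapping[tuple[DeliveryMode, bool], int] = {
    (DeliveryMode.CESAREAN, False): 11,
    (DeliveryMode.CESAREAN, True): 12,
    (DeliveryMode.VAGINAL, False): 14,
    (DeliveryMode.VAGINAL, True): 15,
}

ALL_CONTEXTS = tuple(ClinicalContext(m, a) for (m, a) in CONTEXT_MAX_POINTS)


@dataclass(frozen=True)
class CriterionStatus:
    """Evidence for one criterion: whether and when it was performed.

    ``delay_minutes`` is present exactly when ``state`` is DONE_TIMED and is
    measured from the criterion's anchor event (PPH diagnosis for most timed
    criteria; first-line uterotonic administration for the second-line one).
    """

    state: State
    delay_minutes: float | None = None

    def __post_init__(self) -> None:
        if self.state is State.DONE_TIMED:
            if self.delay_minutes is None:
                raise ValueError("done_timed requires delay_minutes")
            if self.delay_minutes < 0:
                raise ValueError("delay_minutes must be non-negative")
        elif self.delay_minutes is not None:
            raise ValueError(f"delay_minutes not allowed for state {self.state.value}")

    # -- convenience constructors ------------------------------------
    @classmethod
    def done_timed(cls, delay_minutes: float) -> "CriterionStatus":
        return cls(State.DONE_TIMED, float(delay_minutes))

    @classmethod
    def done_timing_unknown(cls) -> "CriterionStatus":
        return cls(State.DONE_TIMING_UNKNOWN)

    @classmethod
    def done_untimed(cls) -> "CriterionStatus":
        return cls(State.DONE_UNTIMED)

    @classmethod
    def not_done(cls) -> "CriterionStatus":
        return cls(State.NOT_DONE)

    @classmethod
    def missing(cls) -> "CriterionStatus":
        return cls(State.MISSING)

    @property
    def is_done(self) -> bool:
        return self.state in _DONE_STATES


@dataclass(frozen=True)
class CareRecord:
    """Per-woman criterion-level care evidence.

    All eight slots are always present; slots inapplicable in the woman's
    context are ignored by the scorer.  The second-line delay is anchored at
    first-line uterotonic administration, every other timed delay at PPH
    diagnosis.
    """

    prophylactic_uterotonic: CriterionStatus
    blood_loss_documented: CriterionStatus
    first_line_uterotonic: CriterionStatus
    hemoglobin_measured: CriterionStatus
    hemostasis_measured: CriterionStatus
    manual_uterine_exam: CriterionStatus
    cervix_vagina_exam: CriterionStatus
    second_line_uterotonic: CriterionStatus

    def status(self, criterion: Criterion) -> CriterionStatus:
        return getattr(self, criterion.value)


NOT_APPLICABLE = "NA"


def classify_context(
    delivery_mode: DeliveryMode | str | None, uterine_atony: bool | None
) -> ClinicalContext:
    """Map (delivery mode, atony flag) to the unique scoring-grid cell.

    Raises :class:`UnscoreableContextError` when either element is missing or
    unrecognised; such records cannot be scored and are counted separately by
    :func:`score_cohort`.
    """
    if delivery_mode is None or uterine_atony is None:
        raise UnscoreableContextError(
            f"unscoreable context: delivery_mode={delivery_mode!r}, "
            f"uterine_atony={uterine_atony!r}"
        )
    try:
        mode = DeliveryMode(delivery_mode)
    except ValueError as exc:
        raise UnscoreableContextError(f"unknown delivery mode {delivery_mode!r}") from exc
    return ClinicalContext(mode, bool(uterine_atony))


def _timed_award(status: CriterionStatus, limit: float, on_time: int) -> int:
    """Full credit iff performed within ``limit`` minutes; else nothing.

    Used for hemoglobin, hemostasis and manual uterine exam, whose grid rows
    are "Done <= limit" vs "Not done or done > limit" — an unknown timing
    therefore earns 0 (an incompletely charted procedure counts as not done).
    """
    if status.state is State.DONE_TIMED and status.delay_minutes <= limit:
        return on_time
    return 0


def evaluate_criterion(
    criterion: Criterion, status: CriterionStatus, context: ClinicalContext
) -> int | str:
    """Points awarded for one criterion in one context, or ``NOT_APPLICABLE``.

    Implements the published weighting grid:

    * prophylactic uterotonic, blood-loss documentation: done 2 / not done 0;
    * first-line uterotonic: <=30 min 2, later (or timing unknown) 1, never 0;
    * hemoglobin, hemostasis: done <=60 min 2, otherwise 0;
    * manual uterine exam (vaginal only): done <=30 min 2, otherwise 0;
    * cervix/vagina exam (vaginal only): done 1 / not done 0;
    * second-line uterotonic: with atony <=30 min after first-line 2 else 0;
      without atony, administered at any time 1, never 0.

    ``State.MISSING`` is scored as not done (chart-documentation convention).
    """
    if criterion in VAGINAL_ONLY_CRITERIA and context.delivery_mode is DeliveryMode.CESAREAN:
        return NOT_APPLICABLE

    s = status.state
    if criterion is Criterion.PROPHYLACTIC_UTEROTONIC:
        return 2 if status.is_done else 0
    if criterion is Criterion.BLOOD_LOSS_DOCUMENTED:
        return 2 if status.is_done else 0
    if criterion is Criterion.FIRST_LINE_UTEROTONIC:
        if s is State.DONE_TIMED:
            return 2 if status.delay_minutes <= TIME_LIMITS_MIN[criterion] else 1
        if status.is_done:
            return 1  # administered, timing unrecorded: partial-credit row
        return 0
    if criterion is Criterion.HEMOGLOBIN_MEASURED:
        return _timed_award(status, TIME_LIMITS_MIN[criterion], 2)
    if criterion is Criterion.HEMOSTASIS_MEASURED:
        return _timed_award(status, TIME_LIMITS_MIN[criterion], 2)
    if criterion is Criterion.MANUAL_UTERINE_EXAM:
        return _timed_award(status, TIME_LIMITS_MIN[criterion], 2)
    if criterion is Criterion.CERVIX_VAGINA_EXAM:
        return 1 if status.is_done else 0
    if criterion is Criterion.SECOND_LINE_UTEROTONIC:
        if context.uterine_atony:
            # Only the on-time row carries points when the uterus is atonic.
            return _timed_award(status, TIME_LIMITS_MIN[criterion], 2)
        return 1 if status.is_done else 0
    raise ValueError(f"unknown criterion {criterion!r}")  # pragma: no cover


@dataclass
class QualityScore:
    """Result of scoring one woman."""

    earned_points: int
    max_points: int
    scoreable: bool
    per_criterion_points: dict[Criterion, int | str]
    missing_substituted: frozenset[Criterion] = field(default_factory=frozenset)
    warnings: tuple[str, ...] = ()

    @property
    def ratio(self) -> float:
        return self.earned_points / self.max_points

    @property
    def percentage(self) -> float:
        return 100.0 * self.ratio


def compute_score(record: CareRecord, context: ClinicalContext) -> QualityScore:
    """Score one woman: sum the applicable criterion awards for her context.

    Never raises on a well-formed :class:`CareRecord`.  When the second-line
    uterotonic is reported with a timing but the first-line drug was never
    given, the delay anchor is undefined; the second-line criterion is then
    scored as administered-late (0 with atony, 1 without) with a warning.
    """
    per: dict[Criterion, int | str] = {}
    missing_subst: set[Criterion] = set()
    warns: list[str] = []
    earned = 0
    first_line = record.first_line_uterotonic
    for criterion in Criterion:
        status = record.status(criterion)
        if (
            criterion is Criterion.SECOND_LINE_UTEROTONIC
            and status.state is State.DONE_TIMED
            and not first_line.is_done
        ):
            # anchor (first-line administration) undefined -> late
            status = CriterionStatus.done_timing_unknown()
            award = 0 if context.uterine_atony else 1
            warns.append("second_line_anchor_undefined")
            per[criterion] = award
            earned += award
            continue
        if status.state is State.MISSING:
            missing_subst.add(criterion)
            status = CriterionStatus.not_done()
        award = evaluate_criterion(criterion, status, context)
        per[criterion] = award
        if award != NOT_APPLICABLE:
            earned += int(award)
    return QualityScore(
        earned_points=earned,
        max_points=context.max_points,
        scoreable=True,
        per_criterion_points=per,
        missing_substituted=frozenset(missing_subst),
        warnings=tuple(warns),
    )


def score_cohort(
    records: Iterable[tuple[CareRecord, ClinicalContext | None]],
    exclude_if_missing_criterion: bool = False,
) -> tuple[np.ndarray, int]:
    """Score a cohort, excluding and counting unscoreable records.

    ``records`` yields ``(care_record, context)`` pairs; a ``None`` context
    marks a record whose scoring-grid cell could not be established.  With
    ``exclude_if_missing_criterion`` records carrying any MISSING criterion
    status are also excluded (mirrors a cohort in which incomplete charts are
    dropped rather than scored as not-done).

    Returns ``(scores, n_unscoreable)`` with ``len(scores) + n_unscoreable``
    equal to the number of input records; scores are ratios in [0, 1].
    """
    scores: list[float] = []
    n_unscoreable = 0
    for care, context in records:
        if context is None:
            n_unscoreable += 1
            continue
        if exclude_if_missing_criterion and any(
            care.status(c).state is State.MISSING for c in Criterion
        ):
            n_unscoreable += 1
            continue
        scores.append(compute_score(care, context).ratio)
    return np.asarray(scores, dtype=float), n_unscoreable


_QUANTILE_METHODS = {"linear", "lower", "nearest"}


@dataclass
class InadequateCareClassification:
    """Cohort-level threshold and per-woman inadequate-care flags."""

    threshold: float
    quantile_level: float
    strict: bool
    flags: np.ndarray
    n_flagged: int

    @property
    def flagged_fraction(self) -> float:
        return self.n_flagged / len(self.flags)


def classify_inadequate(
    scores: Sequence[float] | np.ndarray,
    quantile_level: float = 0.25,
    strict: bool = True,
    method: str = "linear",
) -> InadequateCareClassification:
    """Flag women whose score falls (strictly) below the cohort percentile.

    ``method`` selects the empirical-quantile definition (``linear`` — the
    interpolated default, ``lower`` — the inverse-CDF order statistic, or
    ``nearest``).  With ``strict`` (the default) a score exactly equal to the
    threshold is adequate.  The strictly-below-the-threshold fraction can
    never exceed ``quantile_level`` under the ``lower`` quantile; under
    ``linear`` it can exceed it by at most one observation.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores")
    if not (0.0 <= scores.min() and scores.max() <= 1.0):
        raise ValueError("scores must lie in [0, 1]")
    if method not in _QUANTILE_METHODS:
        raise ValueError(f"unknown quantile method {method!r}")
    threshold = float(np.quantile(scores, quantile_level, method=method))
    flags = scores < threshold if strict else scores <= threshold
    return InadequateCareClassification(
        threshold=threshold,
        quantile_level=quantile_level,
        strict=strict,
        flags=flags,
        n_flagged=int(flags.sum()),
    )
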