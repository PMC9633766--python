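import numpy as np
import pytest

from pphq.scoring import (
    CareRecord,
    ClinicalContext,
    CriterionStatus,
    DeliveryMode,
    State,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_status(state: str, delay=None) -> CriterionStatus:
    if state == "done_timed":
        return CriterionStatus.done_timed(delay)
    return CriterionStatus(State(state))


def make_record(**overrides) -> CareRecord:
    """A fully compliant record (every criterion at maximum credit)."""
    base = dict(
        prophylactic_uterotonic=CriterionStatus.done_untimed(),
        blood_loss_documented=CriterionStatus.done_untimed(),
        first_line_uterotonic=CriterionStatus.done_timed(10),
        hemoglobin_measured=CriterionStatus.done_timed(20),
        hemostasis_measured=CriterionStatus.done_timed(20),
        manual_uterine_exam=CriterionStatus.done_timed(10),
        cervix_vagina_exam=CriterionStatus.done_untimed(),
        second_line_uterotonic=CriterionStatus.done_timed(10),
    )
    base.update(overrides)
    return CareRecord(**base)


@pytest.fixture
def perfect_record():
    return make_record()


VAGINAL_ATONY = ClinicalContext(DeliveryMode.VAGINAL, True)
VAGINAL_NO_ATONY = ClinicalContext(DeliveryMode.VAGINAL, False)
CESAREAN_ATONY = ClinicalContext(DeliveryMode.CESAREAN, True)
CESAREAN_NO_ATONY = ClinicalContext(DeliveryMode.CESAREAN, False)
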