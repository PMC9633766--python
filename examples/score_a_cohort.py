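"""Score a handful of women and flag inadequate care.

Builds a tiny in-memory cohort of six severe-PPH cases, computes each
woman's quality-of-care score (points earned over the maximum for her
clinical context) and classifies scores strictly below the cohort's 25th
percentile as inadequate care.
"""

from pphq import (
    CareRecord,
    CriterionStatus as S,
    classify_context,
    classify_inadequate,
    compute_score,
)

women = [
    # (label, delivery mode, atony?, care record)
    ("fully compliant, vaginal + atony", "vaginal", True, CareRecord(
        prophylactic_uterotonic=S.done_untimed(),
        blood_loss_documented=S.done_untimed(),
        first_line_uterotonic=S.done_timed(12),
        hemoglobin_measured=S.done_timed(40),
        hemostasis_measured=S.done_timed(40),
        manual_uterine_exam=S.done_timed(15),
        cervix_vagina_exam=S.done_untimed(),
        second_line_uterotonic=S.done_timed(20),
    )),
    ("late first-line oxytocin", "vaginal", True, CareRecord(
        prophylactic_uterotonic=S.done_untimed(),
        blood_loss_documented=S.done_untimed(),
        first_line_uterotonic=S.done_timed(45),   # > 30 min: 1 point not 2
        hemoglobin_measured=S.done_timed(40),
        hemostasis_measured=S.done_timed(40),
        manual_uterine_exam=S.done_timed(15),
        cervix_vagina_exam=S.done_untimed(),
        second_line_uterotonic=S.done_timed(20),
    )),
    ("cesarean, no atony, minimal workup", "cesarean", False, CareRecord(
        prophylactic_uterotonic=S.done_untimed(),
        blood_loss_documented=S.not_done(),
        first_line_uterotonic=S.done_timing_unknown(),  # charted, no time
        hemoglobin_measured=S.not_done(),
        hemostasis_measured=S.missing(),                # not noted -> not done
        manual_uterine_exam=S.not_done(),               # NA after cesarean
        cervix_vagina_exam=S.not_done(),                # NA after cesarean
        second_line_uterotonic=S.not_done(),
    )),
    ("cesarean + atony, slow sulprostone", "cesarean", True, CareRecord(
        prophylactic_uterotonic=S.done_untimed(),
        blood_loss_documented=S.done_untimed(),
        first_line_uterotonic=S.done_timed(20),
        hemoglobin_measured=S.done_timed(70),           # > 60 min: 0 points
        hemostasis_measured=S.done_timed(55),
        manual_uterine_exam=S.not_done(),
        cervix_vagina_exam=S.not_done(),
        second_line_uterotonic=S.done_timed(50),        # > 30 min: 0 with atony
    )),
    ("vaginal, nothing charted", "vaginal", True, CareRecord(
        **{f: S.missing() for f in (
            "prophylactic_uterotonic", "blood_loss_documented",
            "first_line_uterotonic", "hemoglobin_measured",
            "hemostasis_measured", "manual_uterine_exam",
            "cervix_vagina_exam", "second_line_uterotonic",
        )}
    )),
    ("vaginal, no atony, good basics", "vaginal", False, CareRecord(
        prophylactic_uterotonic=S.done_untimed(),
        blood_loss_documented=S.done_untimed(),
        first_line_uterotonic=S.done_timed(25),
        hemoglobin_measured=S.done_timed(30),
        hemostasis_measured=S.not_done(),
        manual_uterine_exam=S.done_timed(20),
        cervix_vagina_exam=S.done_untimed(),
        second_line_uterotonic=S.not_done(),
    )),
]

ratios = []
for label, mode, atony, record in women:
    ctx = classify_context(mode, atony)
    qs = compute_score(record, ctx)
    ratios.append(qs.ratio)
    print(f"{label:40s} {qs.earned_points:2d}/{qs.max_points:2d}  = {qs.percentage:5.1f}%")

cls = classify_inadequate(ratios)
print(f"\n25th-percentile threshold: {100 * cls.threshold:.1f}%")
for (label, *_), flag in zip(women, cls.flags):
    print(f"  inadequate care: {str(bool(flag)):5s}  {label}")
# A score below the threshold marks care that missed more of the expected
# management items than three quarters of this (tiny) cohort.
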