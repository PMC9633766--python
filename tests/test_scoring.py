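"""Unit and property tests for the quality-of-care scorer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pphq.scoring import (
    ALL_CONTEXTS,
    CareRecord,
    ClinicalContext,
    Criterion,
    CriterionStatus,
    DeliveryMode,
    NOT_APPLICABLE,
    State,
    UnscoreableContextError,
    classify_context,
    classify_inadequate,
    compute_score,
    evaluate_criterion,
    score_cohort,
)

from conftest import (
    CESAREAN_ATONY,
    CESAREAN_NO_ATONY,
    VAGINAL_ATONY,
    VAGINAL_NO_ATONY,
    make_record,
    make_status,
)
from oracles import ALL_CRITERIA, enumerate_states, oracle_score, quantile_oracle


class TestContext:
    @pytest.mark.parametrize(
        "mode,atony,expected_max",
        [
            ("cesarean", False, 11),
            ("cesarean", True, 12),
            ("vaginal", False, 14),
            ("vaginal", True, 15),
        ],
    )
    def test_max_points_per_context(self, mode, atony, expected_max):
        assert classify_context(mode, atony).max_points == expected_max

    def test_exactly_four_contexts(self):
        assert len(set(ALL_CONTEXTS)) == 4

    @pytest.mark.parametrize(
        "mode,atony", [("vaginal", None), (None, True), ("forceps", True)]
    )
    def test_unscoreable_context_signalled(self, mode, atony):
        with pytest.raises(UnscoreableContextError):
            classify_context(mode, atony)


class TestCriterionStatus:
    def test_delay_requires_done_timed(self):
        with pytest.raises(ValueError):
            CriterionStatus(State.NOT_DONE, 10.0)
        with pytest.raises(ValueError):
            CriterionStatus(State.DONE_TIMED)
        with pytest.raises(ValueError):
            CriterionStatus.done_timed(-5)


class TestEvaluateCriterion:
    @pytest.mark.parametrize(
        "criterion,status,context,expected",
        [
            # first-line uterotonic: late administration earns partial credit
            (Criterion.FIRST_LINE_UTEROTONIC, ("done_timed", 45), VAGINAL_ATONY, 1),
            (Criterion.FIRST_LINE_UTEROTONIC, ("done_timed", 30), CESAREAN_NO_ATONY, 2),
            (Criterion.FIRST_LINE_UTEROTONIC, ("done_timing_unknown", None), VAGINAL_ATONY, 1),
            (Criterion.FIRST_LINE_UTEROTONIC, ("not_done", None), VAGINAL_ATONY, 0),
            # examinations apply only after vaginal delivery
            (Criterion.MANUAL_UTERINE_EXAM, ("done_timed", 10), CESAREAN_ATONY, NOT_APPLICABLE),
            (Criterion.MANUAL_UTERINE_EXAM, ("done_timed", 10), VAGINAL_ATONY, 2),
            (Criterion.MANUAL_UTERINE_EXAM, ("done_timing_unknown", None), VAGINAL_ATONY, 0),
            (Criterion.CERVIX_VAGINA_EXAM, ("done_untimed", None), CESAREAN_NO_ATONY, NOT_APPLICABLE),
            (Criterion.CERVIX_VAGINA_EXAM, ("done_untimed", None), VAGINAL_NO_ATONY, 1),
            # second-line: weighted 2 with atony (on time only), 1 otherwise
            (Criterion.SECOND_LINE_UTEROTONIC, ("done_timed", 20), VAGINAL_ATONY, 2),
            (Criterion.SECOND_LINE_UTEROTONIC, ("done_timed", 40), VAGINAL_ATONY, 0),
            (Criterion.SECOND_LINE_UTEROTONIC, ("done_timed", 40), VAGINAL_NO_ATONY, 1),
            (Criterion.SECOND_LINE_UTEROTONIC, ("done_timing_unknown", None), CESAREAN_NO_ATONY, 1),
            (Criterion.SECOND_LINE_UTEROTONIC, ("done_timing_unknown", None), CESAREAN_ATONY, 0),
            # hemoglobin at the inclusive 60-minute boundary
            (Criterion.HEMOGLOBIN_MEASURED, ("done_timed", 60), VAGINAL_ATONY, 2),
            (Criterion.HEMOGLOBIN_MEASURED, ("done_timed", 61), VAGINAL_ATONY, 0),
            (Criterion.HEMOSTASIS_MEASURED, ("done_timing_unknown", None), VAGINAL_ATONY, 0),
            (Criterion.PROPHYLACTIC_UTEROTONIC, ("done_untimed", None), CESAREAN_ATONY, 2),
            (Criterion.BLOOD_LOSS_DOCUMENTED, ("not_done", None), VAGINAL_NO_ATONY, 0),
        ],
    )
    def test_grid_awards(self, criterion, status, context, expected):
        st_obj = make_status(*status)
        assert evaluate_criterion(criterion, st_obj, context) == expected

    @pytest.mark.parametrize("criterion", list(Criterion))
    @pytest.mark.parametrize("context", ALL_CONTEXTS)
    def test_missing_scores_like_not_done(self, criterion, context):
        missing = evaluate_criterion(criterion, make_status("missing"), context)
        not_done = evaluate_criterion(criterion, make_status("not_done"), context)
        assert missing == not_done

    def test_boundary_inclusive_at_30(self):
        on_time = evaluate_criterion(
            Criterion.MANUAL_UTERINE_EXAM, make_status("done_timed", 30), VAGINAL_ATONY
        )
        late = evaluate_criterion(
            Criterion.MANUAL_UTERINE_EXAM, make_status("done_timed", 30.001), VAGINAL_ATONY
        )
        assert (on_time, late) == (2, 0)


class TestComputeScore:
    def test_all_maximum_vaginal_atony(self):
        qs = compute_score(make_record(), VAGINAL_ATONY)
        assert (qs.earned_points, qs.max_points, qs.ratio) == (15, 15, 1.0)

    def test_nothing_done_cesarean_atony(self):
        nothing = {c.value: make_status("not_done") for c in Criterion}
        qs = compute_score(CareRecord(**nothing), CESAREAN_ATONY)
        assert (qs.earned_points, qs.max_points, qs.ratio) == (0, 12, 0.0)

    def test_late_first_line_loses_one_point(self):
        rec = make_record(first_line_uterotonic=CriterionStatus.done_timed(45))
        qs = compute_score(rec, VAGINAL_ATONY)
        assert qs.earned_points == 14
        assert qs.ratio == pytest.approx(14 / 15)

    def test_all_maximum_cesarean_no_atony(self):
        # prophylactic 2 + blood loss 2 + first-line 2 + Hb 2 + hemostasis 2
        # + second-line administered 1 = 11/11; exams not applicable
        qs = compute_score(make_record(), CESAREAN_NO_ATONY)
        assert (qs.earned_points, qs.max_points, qs.ratio) == (11, 11, 1.0)
        assert qs.per_criterion_points[Criterion.MANUAL_UTERINE_EXAM] == NOT_APPLICABLE
        assert qs.per_criterion_points[Criterion.SECOND_LINE_UTEROTONIC] == 1

    def test_per_criterion_points_sum_to_earned(self):
        rec = make_record(
            hemoglobin_measured=make_status("not_done"),
            second_line_uterotonic=make_status("done_timed", 50),
        )
        for ctx in ALL_CONTEXTS:
            qs = compute_score(rec, ctx)
            applicable = [
                v for v in qs.per_criterion_points.values() if v != NOT_APPLICABLE
            ]
            assert sum(applicable) == qs.earned_points

    def test_missing_substitution_recorded(self):
        rec = make_record(hemostasis_measured=make_status("missing"))
        qs = compute_score(rec, VAGINAL_ATONY)
        assert Criterion.HEMOSTASIS_MEASURED in qs.missing_substituted
        assert qs.earned_points == 13  # missing counted as not done

    def test_second_line_without_first_line_anchor(self):
        rec = make_record(
            first_line_uterotonic=make_status("not_done"),
            second_line_uterotonic=make_status("done_timed", 10),
        )
        with_atony = compute_score(rec, VAGINAL_ATONY)
        without = compute_score(rec, VAGINAL_NO_ATONY)
        assert "second_line_anchor_undefined" in with_atony.warnings
        assert with_atony.per_criterion_points[Criterion.SECOND_LINE_UTEROTONIC] == 0
        assert without.per_criterion_points[Criterion.SECOND_LINE_UTEROTONIC] == 1

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        picks=st.lists(st.integers(0, 5), min_size=8, max_size=8),
        ctx_i=st.integers(0, 3),
    )
    def test_grid_oracle_equivalence_sampled(self, picks, ctx_i):
        """compute_score equals the independent grid transcription."""
        ctx = ALL_CONTEXTS[ctx_i]
        states = {
            c: enumerate_states(c)[i % len(enumerate_states(c))]
            for c, i in zip(ALL_CRITERIA, picks)
        }
        rec = CareRecord(**{c: make_status(s, d) for c, (s, d) in states.items()})
        qs = compute_score(rec, ctx)
        total, maximum = oracle_score(
            states, ctx.delivery_mode.value == "cesarean", ctx.uterine_atony
        )
        assert qs.earned_points == total
        assert qs.max_points == maximum

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        crit=st.sampled_from(ALL_CRITERIA),
        worse_better=st.sampled_from(
            [("not_done", None), ("done_timed", 61), ("done_timed", 31), ("done_timed", 10)]
        ),
        ctx_i=st.integers(0, 3),
    )
    def test_monotone_improvement_never_lowers_score(self, crit, worse_better, ctx_i):
        """Moving one criterion from not-done toward on-time never lowers the score."""
        ctx = ALL_CONTEXTS[ctx_i]
        ladder = [("not_done", None), ("done_timed", 61), ("done_timed", 31), ("done_timed", 10)]
        start = ladder.index(worse_better)
        scores = []
        for state, delay in ladder[start:]:
            rec = make_record(**{crit: make_status(state, delay)})
            scores.append(compute_score(rec, ctx).earned_points)
        assert scores == sorted(scores)


class TestScoreCohort:
    def test_counts_unscoreable(self, perfect_record):
        items = [(perfect_record, VAGINAL_ATONY)] * 5 + [(perfect_record, None)] * 2
        scores, n_unscoreable = score_cohort(items)
        assert len(scores) == 5 and n_unscoreable == 2

    def test_empty_cohort(self):
        scores, n = score_cohort([])
        assert len(scores) == 0 and n == 0

    def test_all_scoreable(self, perfect_record):
        scores, n = score_cohort([(perfect_record, CESAREAN_ATONY)] * 3)
        assert n == 0 and np.allclose(scores, 1.0)

    def test_exclusion_on_missing_criterion_option(self):
        rec = make_record(hemoglobin_measured=make_status("missing"))
        items = [(rec, VAGINAL_ATONY), (make_record(), VAGINAL_ATONY)]
        scores_default, n_default = score_cohort(items)
        scores_strict, n_strict = score_cohort(items, exclude_if_missing_criterion=True)
        assert (len(scores_default), n_default) == (2, 0)
        assert (len(scores_strict), n_strict) == (1, 1)


class TestClassifyInadequate:
    def test_quantile_oracle_example(self):
        scores = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        expected_threshold = quantile_oracle(scores, 0.25)
        cls = classify_inadequate(scores)
        assert cls.threshold == pytest.approx(expected_threshold)
        assert cls.n_flagged == 2
        assert list(cls.flags) == [True, True, False, False, False, False, False, False]

    def test_constant_scores_flag_nothing(self):
        cls = classify_inadequate([0.5] * 40)
        assert cls.n_flagged == 0

    def test_non_strict_includes_threshold_ties(self):
        scores = [0.2] * 10 + [0.8] * 30
        strict = classify_inadequate(scores, strict=True, method="lower")
        lte = classify_inadequate(scores, strict=False, method="lower")
        assert strict.n_flagged == 0
        assert lte.n_flagged == 10

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no scores"):
            classify_inadequate([])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200),
    )
    def test_strict_lower_quantile_bound(self, scores):
        """Strictly-below flags never exceed the level under the lower quantile."""
        cls = classify_inadequate(scores, method="lower")
        assert cls.n_flagged <= 0.25 * len(scores)

    def test_threshold_reproducible_from_vector(self, rng):
        scores = rng.random(500)
        a = classify_inadequate(scores)
        b = classify_inadequate(scores)
        assert a.threshold == b.threshold and a.n_flagged == b.n_flagged
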