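"""Independent oracles used by the test suite.

``oracle_award`` is a second, independent transcription of the published
weighting grid (row labels read straight off the table), kept deliberately
separate from the package's scorer so the two can be compared
cell-for-cell.  ``enumerate_states`` spans the complete well-formed state
space of each criterion: for timed criteria, delays at the cut-off minus
one minute, at the cut-off, and one minute past it, plus
performed-with-unknown-timing, not-performed and missing; for untimed
criteria performed / not-performed / missing.
"""

from __future__ import annotations

import itertools

import numpy as np

TIMED = {
    "first_line_uterotonic": 30,
    "hemoglobin_measured": 60,
    "hemostasis_measured": 60,
    "manual_uterine_exam": 30,
    "second_line_uterotonic": 30,
}
UNTIMED = ("prophylactic_uterotonic", "blood_loss_documented", "cervix_vagina_exam")
ALL_CRITERIA = (
    "prophylactic_uterotonic",
    "blood_loss_documented",
    "first_line_uterotonic",
    "hemoglobin_measured",
    "hemostasis_measured",
    "manual_uterine_exam",
    "cervix_vagina_exam",
    "second_line_uterotonic",
)

_DONE = ("done_timed", "done_timing_unknown", "done_untimed")


def oracle_award(crit, state, delay, cesarean, atony, first_line_done):
    """Points for one criterion cell, or None where the grid prints NA."""
    done = state in _DONE
    if crit == "prophylactic_uterotonic":
        return 2 if done else 0
    if crit == "blood_loss_documented":
        return 2 if done else 0
    if crit == "first_line_uterotonic":
        if state == "done_timed":
            return 2 if delay <= 30 else 1
        return 1 if done else 0
    if crit in ("hemoglobin_measured", "hemostasis_measured"):
        return 2 if (state == "done_timed" and delay <= 60) else 0
    if crit == "manual_uterine_exam":
        if cesarean:
            return None
        return 2 if (state == "done_timed" and delay <= 30) else 0
    if crit == "cervix_vagina_exam":
        if cesarean:
            return None
        return 1 if done else 0
    if crit == "second_line_uterotonic":
        if state == "done_timed" and not first_line_done:
            # timing anchor (first-line administration) undefined:
            # counts as administered with unusable timing
            return 0 if atony else 1
        if atony:
            return 2 if (state == "done_timed" and delay <= 30) else 0
        return 1 if done else 0
    raise ValueError(crit)


def oracle_score(states, cesarean, atony):
    """Total points and maximum for a full record; independent of the scorer."""
    first_line_done = states["first_line_uterotonic"][0] in _DONE
    total = 0
    for crit, (state, delay) in states.items():
        a = oracle_award(crit, state, delay, cesarean, atony, first_line_done)
        if a is not None:
            total += a
    maximum = {
        (True, False): 11,
        (True, True): 12,
        (False, False): 14,
        (False, True): 15,
    }[(cesarean, atony)]
    return total, maximum


def enumerate_states(crit):
    """Complete well-formed state space of one criterion."""
    if crit in TIMED:
        limit = TIMED[crit]
        return [
            ("done_timed", limit - 1),
            ("done_timed", limit),
            ("done_timed", limit + 1),
            ("done_timing_unknown", None),
            ("not_done", None),
            ("missing", None),
        ]
    return [("done_untimed", None), ("not_done", None), ("missing", None)]


def enumerate_records():
    """Every combination of criterion states (839,808 per the state spaces)."""
    spaces = [enumerate_states(c) for c in ALL_CRITERIA]
    for combo in itertools.product(*spaces):
        yield dict(zip(ALL_CRITERIA, combo))


def quantile_oracle(values, level):
    """Brute-force linear-interpolation quantile on the sorted vector."""
    xs = sorted(values)
    h = (len(xs) - 1) * level
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])
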