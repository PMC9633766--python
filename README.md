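# pphq — quantitative quality-of-care assessment for severe postpartum hemorrhage

Postpartum hemorrhage (PPH) is the leading preventable cause of maternal
mortality, and much of the harm from severe PPH traces back to gaps in
*first-line* management: a prophylactic uterotonic not given, blood loss
not charted, oxytocin or laboratory workup started too late, sulprostone
delayed.  Auditing single items misses the overall picture, and global
expert review is subjective.  `pphq` implements a reproducible composite
score for the global quality of first-line PPH care, together with the
analysis machinery needed to study *which maternity units* deliver
inadequate care.  It is written for perinatal epidemiologists, quality-of-care
researchers and biostatisticians working with clustered clinical cohorts.

## The score

Eight expert-weighted criteria of prevention and first-line treatment are
combined into a single per-woman figure.  Which criteria apply — and the
attainable maximum — depend on the clinical context, the cell of
(delivery mode) × (uterine atony):

| criterion (weight) | cesarean, no atony | cesarean, atony | vaginal, no atony | vaginal, atony |
|---|---|---|---|---|
| prophylactic uterotonic, 3rd stage (2) | ✓ | ✓ | ✓ | ✓ |
| blood-loss estimate in the chart (2) | ✓ | ✓ | ✓ | ✓ |
| first-line uterotonic ≤ 30 min (2; later 1) | ✓ | ✓ | ✓ | ✓ |
| hemoglobin measured ≤ 60 min (2) | ✓ | ✓ | ✓ | ✓ |
| hemostasis measured ≤ 60 min (2) | ✓ | ✓ | ✓ | ✓ |
| manual uterine examination ≤ 30 min (2) | — | — | ✓ | ✓ |
| cervix/vagina examination (1) | — | — | ✓ | ✓ |
| second-line uterotonic (atony: ≤ 30 min 2; no atony: any time 1) | ✓ | ✓ | ✓ | ✓ |
| **maximum points** | **11** | **12** | **14** | **15** |

The quality score is `earned points / maximum points`; delays are measured
from PPH diagnosis, except the second-line uterotonic, measured from
first-line administration.  Boundaries are inclusive (exactly 30 or 60
minutes earns full credit); a procedure not noted in the chart counts as
not done.  **Inadequate care** is a score strictly below the cohort's 25th
percentile.

Unit-level determinants of inadequate care are estimated with
random-intercept logistic regression,

&nbsp;&nbsp;&nbsp;&nbsp;logit P(y<sub>ij</sub> = 1 | u<sub>j</sub>) = x<sub>ij</sub>ᵀβ + u<sub>j</sub>, &nbsp; u<sub>j</sub> ~ N(0, σ²),

maximised by adaptive Gauss–Hermite quadrature (15 nodes), one model per
unit characteristic (status, delivery volume, level of care, 24/24 on-site
obstetrician / anesthesiologist), adjusted for individual confounders and
optionally stratified by delivery mode.  Missing covariates are handled by
multiple imputation with chained equations (m = 12) and Rubin's rules.
A synthetic-cohort generator (units → women → criterion-level care events,
with a shared unit latent quality effect) lets every stage run end to end
without patient data.

## Worked example

```python
from pphq import CareRecord, CriterionStatus as S, classify_context, compute_score

ctx = classify_context("vaginal", uterine_atony=True)      # max 15 points
record = CareRecord(
    prophylactic_uterotonic=S.done_untimed(),
    blood_loss_documented=S.done_untimed(),
    first_line_uterotonic=S.done_timed(45),   # late: 1 point instead of 2
    hemoglobin_measured=S.done_timed(40),
    hemostasis_measured=S.done_timed(40),
    manual_uterine_exam=S.done_timed(15),
    cervix_vagina_exam=S.done_untimed(),
    second_line_uterotonic=S.done_timed(20),
)
qs = compute_score(record, ctx)
print(qs.earned_points, qs.max_points, round(qs.percentage, 1))
```

prints `14 15 93.3` — everything was done on time except the first-line
uterotonic at 45 minutes, which keeps partial credit.  Running the cohort
example, `python examples/simulate_and_describe.py`:

```
119 units, 962 women; cesarean 31.9%, atony 70.7%

score threshold (25th pct): 60.0%  -> 228 of 962 women flagged (23.7%)

per-criterion compliance (numerator/denominator, %):
                          item   n   N  percent
       prophylactic_uterotonic 862 962     89.6
         blood_loss_documented 816 962     84.8
          first_line_any_delay 851 962     88.5
               first_line_le30 711 962     73.9
               ...
```

Each compliance row is the share of women, within the criterion's
applicable subgroup (e.g. vaginal deliveries only for the examinations),
whose chart documents the item inside its delay cut-off.  The other
examples show determinant recovery (`examples/unit_determinants.py`) and
imputation pooling (`examples/impute_and_pool.py`).

A thin CLI mirrors the pipeline stages:

```bash
pphq simulate --seed 1 --out-cohort cohort.csv --out-units units.csv
pphq score    --cohort cohort.csv --out scores.csv --summary summary.json
pphq analyze  --scores scores.csv --cohort cohort.csv --units units.csv \
              --stratum vaginal --impute --out results.json
pphq report   --cohort cohort.csv --scores scores.csv --units units.csv \
              --out-compliance compliance.csv
```

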