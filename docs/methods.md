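# Methods

## The quality-of-care score

The scorer encodes a fixed expert-weighted grid over eight criteria of PPH
prevention and first-line management.  Its design choices, where the grid
alone does not decide behaviour:

* **Timing boundaries are closed.**  "Within 30 minutes" and "within 60
  minutes" include the boundary: a delay of exactly 30 (or 60) minutes
  earns full credit, 30 + ε does not.
* **Chart-documentation convention.**  A criterion recorded as missing is
  scored as not done — in a chart audit, care that is not documented
  cannot be credited — but the substitution is recorded per record
  (`QualityScore.missing_substituted`), and cohorts can instead be scored
  with `exclude_if_missing_criterion=True`, which drops such records and
  counts them as unscoreable.  Records whose clinical context (delivery
  mode or atony flag) is missing are always unscoreable: without the
  context the applicable criteria and the maximum are undefined.
* **Performed with unknown timing.**  Criteria that carry a partial-credit
  "administered at any time" row — the first-line uterotonic everywhere,
  the second-line uterotonic when there is no atony — earn that partial
  credit (1 point) when the procedure is documented but untimed.  Purely
  timed criteria (hemoglobin, hemostasis, manual examination) earn 0: only
  a documented on-time delay can satisfy them.  This reconciles the
  not-done convention with the existence of the partial-credit rows.
* **Second-line asymmetry, as printed.**  With uterine atony the
  second-line uterotonic scores 2 only when given ≤ 30 minutes after the
  first-line drug and 0 otherwise; without atony it scores 1 for
  administration at any time.  A second-line drug given more than 30
  minutes after oxytocin in an atonic woman therefore earns less (0) than
  the same delay in a non-atonic woman (1).  The grid totals
  (11/12/14/15) are only consistent with this reading, so it is
  implemented as printed.
* **Undefined timing anchor.**  The second-line delay is anchored at
  first-line administration.  If the first-line drug was never given but a
  timed second-line administration is recorded, the anchor is undefined;
  the criterion is scored as administered-late (0 with atony, 1 without)
  and the record carries a `second_line_anchor_undefined` warning.
* **Exact arithmetic.**  Scores are kept as integer (earned, maximum)
  pairs beside the float ratio; report percentages round half away from
  zero to one decimal.

**Inadequate care** is a score strictly below the cohort's 25th
percentile.  The empirical quantile definition is configurable: linear
interpolation between order statistics (the scientific-stack default and
the package default), the inverse-CDF order statistic (`"lower"`), or
nearest order statistic.  The choice matters at the margins: under the
`lower` quantile the strictly-below flag rate provably never exceeds the
quantile level; under linear interpolation it can exceed it by at most one
observation (the interpolated value can sit strictly above the relevant
order statistic).  A non-strict (≤) comparison is available as a flag.

## Eligibility

Severity is a union of inclusive thresholds: blood loss ≥ 1500 mL,
≥ 4 red-cell units transfused, hemostatic surgery/embolization, hemoglobin
nadir ≤ 7 g/dL, platelets ≤ 50,000/mm³, DIC, organ failure, ICU admission,
or death.  Missing indicators never qualify — inclusion requires positive
evidence, consistent with prospective case identification.  Etiology
exclusions (surgical wound without atony, abnormally invasive placenta,
uterine rupture, amniotic-fluid embolism, vaginal thrombus without atony,
uterine inversion, secondary PPH, PPH at home) are applied after severity
as a *union*: flags may co-occur, so per-flag exclusion tallies can sum to
more than the number of women excluded, and the flow accounting never
assumes otherwise.

## Random-intercept logistic regression

Determinant models are logit P(y_ij = 1 | u_j) = x_ij'β + u_j with
u_j ~ N(0, σ²) per maternity unit, estimated by maximum marginal
likelihood.  The per-cluster integral is approximated by *adaptive*
Gauss–Hermite quadrature: each cluster's integrand is recentred at its
posterior mode (vectorised Newton iteration across clusters) and rescaled
by the curvature there, then evaluated on 15 Hermite nodes with
log-sum-exp accumulation.  Fifteen nodes are accurate to well below 1e-6
on cohort-sized clusters (doubling the node count moves the optimum
log-likelihood by < 1e-4), while keeping a full model fit around a quarter
of a second.  A Laplace approximation (`method="laplace"`) is the one-node
fallback.

Numerical choices: optimisation is L-BFGS-B over (β, σ) with σ bounded
below by 0; at σ < 1e-6 the likelihood is evaluated in its exact
collapsed (ordinary logistic) form, so the boundary is handled without
singularities.  Warm starts come from a plain `statsmodels` logistic fit
(zeros under separation).  A boundary estimate σ̂ ≈ 0 is reported
explicitly (`sigma_at_boundary`); note that finite samples generated with
σ = 0 legitimately yield σ̂ > 0 under marginal ML, so the collapse to
ordinary logistic holds at the boundary, not for every such sample.
Standard errors are from the numerical observed information at the
optimum (β block only when σ̂ is at the boundary, where the Wald
approximation for σ fails); confidence intervals are Wald, 95%, on the
log-odds scale, exponentiated into odds ratios.  Reference levels (public
university status, ≥ 3500 deliveries/year, level-3 care, 24/24 presence of
each specialist, born in France, primiparous, no risk factor) are absorbed
into the intercept and reported with OR exactly 1 and no interval.

The model suite mirrors the analysis design: because unit characteristics
are strongly interrelated (small units tend to be private, level 1, and
thinly staffed), each characteristic gets its own crude model
(characteristic + random intercept) and its own adjusted model
(+ risk profile, country of birth, parity/previous cesarean), rather than
one joint model; collinearity is screened by variance inflation factors
(VIF_k = 1/(1−R²_k)).  The vaginal stratum additionally fits the combined
status + volume model.  Crude models keep the random intercept: the
clustering is a property of the sampling design, not of the adjustment.
Strata with too few events yield `converged=False` rows; the suite always
completes.  Singleton clusters are not excluded — the marginal likelihood
handles them — though they contribute little to σ̂ (a documented
limitation).

## Multiple imputation

Chained equations with m = 12 completed datasets and 10 cycles by default.
Every analysis variable enters every conditional model; per-type defaults
are logistic for binary variables, multinomial logistic for unordered
categoricals (the relevant case here: country of birth), and predictive
mean matching with 5 donors for numeric ones.  Parameter uncertainty is
approximated by fitting each conditional model on a bootstrap resample of
the observed rows before drawing.  Observed cells are never modified, and
a fixed seed makes the full set of imputations bit-reproducible.
Estimates are pooled on the log-odds scale by Rubin's rules
(T = W + (1 + 1/m)B, classical degrees of freedom
(m−1)(1 + W/((1+1/m)B))²; with B = 0 the df are infinite and the normal
quantile is used).  A Barnard–Rubin small-sample df adjustment is not
implemented; with m = 12 and cohort-scale n the classical df are adequate.

## Synthetic cohort generator

The generator emulates the study conditions of a French population-based
severe-PPH cohort: 119 maternity units whose joint characteristic
distribution (status × level × volume band × staffing) is chosen so that
the *women-level* margins — units weighted by how many cohort women they
contribute — land near the published description (status ≈ 40/45/15%
university/other-public/private, level of care ≈ 35/44/21%, volume
≈ 18/43/26/13%, 24/24 obstetrician ≈ 78%, anesthesiologist ≈ 91%); about
1100 women with 35.7% cesarean deliveries and 69.8% uterine atony; and
country of birth blanked missing-at-random at 9.6% overall, with the
missingness probability depending only on observed covariates (private
unit, age < 25) so MICE's assumption holds by construction and the per-row
probability is returned for verification.

Care events follow a shared-latent-quality model: one u_j ~ N(0, σ_u²)
per unit (default σ_u = 0.5, a moderate intraclass correlation on the
logit scale) shifts the compliance log-odds of *every* criterion for that
unit's women, generating realistic within-unit correlation of the
inadequate-care outcome; configurable `effect_map` entries add log-odds
shifts per unit-characteristic level (all zero by default — effects are
injected explicitly in recovery experiments).  Per-criterion base
compliance probabilities are calibrated to the published per-item levels
(e.g. 91.7% prophylactic uterotonic, 88.9% first-line administration);
delays are log-normal in minutes with medians and spreads set so the
within-cut-off shares echo the published table (e.g. first-line median 16
minutes, log-SD 0.7 ⇒ ~72% within 30 minutes).  Because the unit effect
enters on the logit scale, marginal compliance is attenuated toward 50%
by roughly one percentage point relative to the base rates at the default
σ_u; the base rates are exact when σ_u = 0.

What the generator does **not** emulate: the real joint distribution of
maternal covariates beyond the printed margins (covariates are drawn
independently), geographic or temporal structure, correlation between
criterion timings within a woman, and etiology-specific care pathways.
Passing recovery tests therefore demonstrate that the pipeline detects
unit-level signal under a faithful nested-data-generating mechanism, not
that any particular real-world estimate is reproduced — the original
individual-level cohort is not public, and the published regression
estimates are deliberately not a target.

## Problem sizes

Default experiment sizes were chosen to make the full suite comfortably
reproducible on a single core: the exhaustive grid check enumerates all
839,808 well-formed criterion-state combinations across the four contexts;
fitter recovery uses 200 replicates of 120 clusters × 10 women; end-to-end
effect recovery uses 50 replicates of full default cohorts (~1100 women);
the acceptance script's pipeline runs one default cohort, a 12-imputation
pooled model, and 25 recovery replicates.
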