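# Methods

## The risk model

The calculator is a Cox proportional-hazards score with fixed, published
coefficients; nothing is re-estimated at screening time. Covariates are
coded against explicit reference levels (female, White ethnicity, ARMS
index diagnosis), so the reference subject at age 0 has linear predictor
0. Age enters linearly and uncentred, in years at the index date; the
age-by-gender interaction applies the per-year increment −0.009 to males
only. Category labels are exact strings and unknown labels are errors —
nothing is ever silently mapped.

Absolute risk requires a baseline survivor function S0, which the
published coefficient table does not include. We therefore treat S0 as
configuration: an exponential baseline by default, with two calibration
routes.

* `calibrate_exponential_baseline` (the packaged default model): the rate
  is solved in closed form so that a 25-year-old female, White, ARMS
  subject has a 20% two-year risk (both the subject and the target risk
  are arguments).
* `calibrate_baseline_to_incidence` (the cohort generator's default): the
  rate is solved by root-finding so that the *expected* six-month event
  proportion of the configured covariate mixture equals a population
  anchor (default 1.04%, the deployment's observed screened-population
  value). The expectation uses a fixed internal quasi-sample, so the
  result is deterministic for a given configuration.

These two routes give different rates (2.38e-4 vs 1.18e-4 per day); which
one a study uses is a config decision. `configs/replication.yaml`
scores with the incidence-calibrated baseline (`model.baseline: cohort`)
so that generated outcomes and computed risks share one scale.
Consequences worth stating plainly: risk *rankings* and every
rank-based quantity (concordance, relative detection ordering) depend
only on the coefficients, while absolute risks — and therefore the
detection rate at the 5% threshold — are baseline-dependent. With the
incidence-anchored exponential baseline the simulated detection rate is
≈17% of intakes, versus ≈3% in the deployed system; matching that would
require the deployed system's unpublished, non-exponential S0.

A step-function S0 is supported as an alternative form (no extrapolation
past its last step); the default is exponential because a single
published anchor cannot identify more than one parameter.

## Screening semantics

Weeks are 7-day blocks from the study start date; a patient enters at the
week containing their index date. Eligibility is age ≥ 14 ("older than
14" is implemented inclusively, matching the recruitment floor stated by
the source study), a non-organic non-psychotic index diagnosis (the 11
calculator clusters, with `Organic` and `Psychotic` accepted as input
labels solely so ineligibility is testable), patient contact details on
record, and entry within the study window. Ineligibility is a value with
a reason, not an error.

Risk is computed once per patient, at the first week all four predictors
are present, from covariates at the index date; it is not re-scored in
later weeks. Predictor availability is an offset in weeks from the
patient's entry week (0 = present at entry, infinity/empty cell = never).
The detection threshold is inclusive (risk ≥ 0.05 detects), and the
two-year horizon is measured from the index date regardless of how long
missing predictors delayed scoring — the delayed-screening alternative
(horizon from screening date) was considered and rejected because the
calculator's covariates are all frozen at index.

The three-month diagnostic-lag filter (used by the retrospective model
variant) removes only patients with an *observed* event before 90 days;
early-censored patients without an event are retained, since only
observed early converters can be identified in a real registry.

## Alert workflow

Each detection opens a case. Absent clinician contact terminates the case
immediately (no prompt); an `incorrect` contact behaves identically to a
valid one from the state machine's point of view, with the third email
understood as routed to the alternate contact. Four stages escalate at
one-week gaps — email 1, reminder email 2, email 3, phone — because the
deployment's response counts are reported over exactly these four
channels. Response at each stage is Bernoulli; personalization (patient
name vs trust identifier) and borough outreach multiply the stage's
response *odds*.

Default behaviour parameters were calibrated analytically, before any
simulation was run, to the deployment's printed aggregates: the odds
effects are the published ORs (2.35 personalization, 2.02 outreach), and
the per-stage base probabilities (0.1504, 0.1314, 0.0490, 0.3883 for the
trust-ID/no-outreach stratum) were solved sequentially so the expected
responder counts among 115 prompts with the deployed mix (75/115 named,
34/115 outreach borough) equal the observed 33/20/6/30. The implied
marginal response rates land close to the printed ones (named/trust email
response 0.598/0.355 vs 0.587/0.375; outreach/no-outreach overall
0.881/0.729 vs 0.853/0.741). Note that per-stage odds effects aggregate
to a *larger* whole-course odds ratio, so simulated ORs centre somewhat
above the per-stage inputs.

Exclusion (probability 18/89 overall, split across the reported
categories in proportions 10:4:2:1:1) is decided before referral
(probability 39/71). Non-referral reasons are a two-level tag
(`acute_phase`, the predominant reported reason, with default share 0.7;
everything else `other`) because the detailed breakdown was never
published.

## Synthetic cohorts

Factors are sampled independently per patient from the screened
population's published marginals — only marginals were published; a joint
table can be supplied by overriding the frequency dicts. Two published
percentages deserve a note: the substance-use row prints 1.64% against a
count of 545/3722 (= 14.64%, an evident typo — the counts, which sum
exactly to 3722, are used), and ARMS has no screened-column row, so its
default frequency is 0 while remaining the model's reference level.

Ages are normal (mean 37.5, SD 18.4) truncated below at 14. Missingness:
35% of intakes are incomplete at entry; the late field is ethnicity
(50%), diagnosis (30%) or both (20%) — a choice, since only the 35%
aggregate was published — and completion is a weekly memoryless process
(default weekly probability 0.25, i.e. median delay 3 weeks, chosen as a
realistic records-lag scale). Age and gender are assumed present at
entry.

Outcomes are drawn from the risk model itself by inverse transform
(exponential baseline: T = −ln U / (rate·e^lp)); censoring is the earlier
of administrative follow-up end (default 730 days after entry) and an
exponential attrition draw (default 1.2e-4/day, matching ≈2% loss by six
months). Exactly one of event/censoring terminates follow-up, and all
times are integer days (events rounded up). All randomness flows from a
single master seed through named SeedSequence substreams (cohort,
outcomes, alert behaviour), so runs regenerate identically.

What the generator does *not* emulate: correlations between demographics
and diagnosis (only marginals), age-dependent diagnosis mixes,
non-proportional hazards or time-varying covariates, informative
censoring, and seasonal intake patterns. Tests passing on these cohorts
show the pipeline's mechanics and the estimators' calibration under the
model's own assumptions — not that the calculator is accurate on real
EHRs, which requires external validation data this package deliberately
does not model. The deployed detected-stratum six-month incidence (~9%)
is similarly not reproduced by the default simulation (~3%): with an
exponential baseline and the published coefficients, calibrating the
screened population's incidence to 1% fixes the detected stratum's, and
the observed gap would need the unpublished baseline's shape.

## Statistical conventions

* Fisher's exact test: two-sided p by summing hypergeometric point
  probabilities ≤ the observed one; the odds ratio is the conditional
  MLE with the exact central conditional CI (this convention — not the
  sample cross-product ratio, which gives 2.37/2.03 — reproduces the
  published 2.35 and 2.02 from the published counts). Degenerate outcome
  margins yield p = 1 with the OR flagged undefined.
* t-tests from summary statistics are Welch's by default with
  Welch-Satterthwaite df (this reproduces the published t = −0.78 from
  the age summaries); pooled variance is an option.
* Kaplan-Meier: product-limit over distinct event times with events
  preceding censorings at ties; Greenwood variance
  S(t)²·Σ d/(n(n−d)); 95% CI on the linear scale, clipped to [0, 1]
  (complementary log-log offered as `ci_scale="loglog"`). Cumulative
  incidence is 1 − S with the CI mirrored; queries past the last observed
  time carry the last estimate forward and are flagged extrapolated.
* Log-rank: the standard two-group O−E/V chi-square with 1 df over pooled
  event times, hypergeometric variance at each time.
* Harrell's C: pairs are comparable when the shorter time is an event
  (time ties comparable only when exactly one member is an event); score
  ties count 1/2; no comparable pairs is an explicit error, not 0.5.
* Conventions used throughout: six months = 183 days, two years = 730
  days; reported percentages rounded to 1 dp (2 dp where the source
  prints 2).

## Numerical choices

The Cox partial-likelihood fitter uses Newton-Raphson with Efron's tie
correction by default (day-granular synthetic data is heavily tied;
Breslow is retained for cross-checking). Raw Newton steps are capped at 2
per coordinate — sparse diagnosis dummies otherwise overshoot
catastrophically on the first iteration — with step-halving to guarantee
ascent; linear predictors are clipped at ±500 before exponentiation.
Standard errors come from the inverse observed information. A coefficient
drifting past 20 in absolute value raises a separation error; a
step-halving stall on a numerically flat likelihood is accepted as
convergence, anything else raises a convergence error carrying the
iteration count.

## Validation problem sizes

The suite validates parameter recovery on a 30,000-patient cohort
followed over the calculator's full 1–6-year outcome window (2,190 days,
≈2,700 events, so every diagnosis cluster accrues events), requiring at
least 15 of the 17 coefficients inside their 95% Wald intervals;
log-rank type-I error is checked over 10,000 label permutations of a
400-subject null dataset (rejection rate 0.05 ± 0.01); Kaplan-Meier and
concordance implementations are compared with brute-force enumeration up
to n = 500 and 200 respectively, and against lifelines; and the
personalization odds ratio is replicated over 1,000 simulated alert
studies at the deployed scale (115 prompts), whose median must bracket
the published 2.35 within [1.5, 3.5].

## Known limitations

Absolute risks are configuration-dependent (no published S0); the
screened-vs-detected sex odds ratio printed by the source study (1.04) is
not reproducible from any arrangement of its printed counts and is not
used; exact ICD-10 code-to-cluster mappings are out of scope (clusters
are taken as given labels); and the second email's trigger and recipient
were never described, so the reminder stage is a modelling choice
reconciling the described escalation with the four reported response
channels.
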