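# psyscreen

A desk-scale re-implementation of a transdiagnostic psychosis-risk
calculator embedded in an automatic electronic-health-record (EHR)
screening loop, together with the clinician alert-escalation workflow and
the feasibility statistics of its deployment study.

It is aimed at researchers in precision psychiatry and clinical prediction
modelling who want to study *deployment* questions — who gets screened and
when, how missing predictors delay scoring, how clinicians respond to
alerts — without access to real patient records: every input can be
simulated under the published study's conditions.

## The model

The calculator is a Cox proportional-hazards risk score over routinely
collected predictors: age at the index diagnosis, gender, an
age-by-gender interaction, self-assigned ethnicity (5 levels, White as
reference) and the ICD-10 index-diagnosis cluster (11 levels, the at-risk
mental state ARMS as reference). With published coefficients β the linear
predictor of subject *x* is

    lp(x) = β_age·age + β_male·[male] + β_age×male·age·[male]
            + β_ethnicity(e) + β_diagnosis(d)

and the absolute risk of a psychotic disorder by horizon *t* follows the
usual survivor transform

    risk(t | x) = 1 − S0(t)^exp(lp(x))

where S0 is the baseline survivor function of the reference subject. The
published model does not come with S0, so it is configurable (an
exponential baseline calibrated to a stated reference risk by default) and
absolute risks are documented as configuration-dependent; risk rankings
depend only on the coefficients.

Around the score sit four more components, each its own module:

* `screening_engine` — eligibility rules (age ≥ 14, non-organic
  non-psychotic index diagnosis, contact details, study window) and the
  weekly loop that re-checks predictor availability and screens each
  patient once, raising a detection at ≥ 5% two-year risk (inclusive).
* `alert_workflow` — the escalation state machine per detection: first
  email → reminder → third email to the alternate contact → phone calls,
  one stage per week, with alert personalization and borough outreach as
  odds modifiers on response; then exclusion and referral decisions.
* `feasibility_stats` — adherence, channel distributions, two-tailed
  Fisher's exact test with the conditional-MLE odds ratio and exact CI,
  Kaplan-Meier curves with Greenwood variance, cumulative incidence, the
  log-rank test, and Welch's t from summary statistics.
* `cohort_synth` — synthetic EHR cohorts with the screened population's
  demographic marginals, ~35% predictor incompleteness at entry, outcomes
  drawn from the calculator itself, censoring, and clinician behaviour;
  plus a deterministic fixture reproducing the deployment's alert funnel.

`risk_model` additionally provides Harrell's concordance index and a Cox
partial-likelihood fitter (Efron/Breslow ties) used to verify that
synthetic cohorts give the generating coefficients back.

## Worked example

Report on the packaged funnel fixture — the deployment's published
numbers frozen as data:

```sh
psyscreen report --config configs/replication.yaml --seed 1 \
    --out runs/fixture --fixture published-funnel
```

```text
psyscreen feasibility report (schema v1, source: published-funnel-fixture)
funnel: detected=117 no_contact=2 prompted=115 responded=89 excluded=18 decisions=71 referred=39
adherence: 77.4%
responses by channel: EMAIL1 33 (37.1%), EMAIL2 20 (22.5%), EMAIL3 6 (6.7%), PHONE 30 (33.7%)
personalization: OR 2.35 (95%CI 1.00-5.64), p = 0.034
outreach: OR 2.02 (95%CI 0.65-7.55), p = 0.229
six-month cumulative incidence, screened: 0.010 (95%CI 0.007-0.014; 3602 still at risk)
six-month cumulative incidence, detected: 0.089 (95%CI 0.034-0.145; 92 still at risk)
age, screened vs detected: t = -0.78, p = 0.437
```

Reading it: of 117 detections, 2 had no clinician contact on record, so
115 prompts were sent; 89 clinicians responded (adherence 77.4%), 18
patients were excluded on clinical grounds, and 39 of the remaining 71
decisions were referrals. Personalised alerts roughly doubled the odds of
an email response (OR 2.35); borough outreach showed a similar but
non-significant effect (OR 2.02). The six-month cumulative incidence of
psychosis was ~1% among all screened and ~9% among those detected — the
risk score concentrates transitions by an order of magnitude.

A fully simulated study under the same conditions (synthetic cohort of
3722 intakes, weekly screening, stochastic clinician behaviour):

```sh
psyscreen run --config configs/replication.yaml --seed 1 --out runs/sim
```

```text
psyscreen feasibility report (schema v1, source: simulation)
funnel: detected=626 no_contact=8 prompted=618 responded=490 excluded=106 decisions=384 referred=194
adherence: 79.3%
responses by channel: EMAIL1 188 (38.4%), EMAIL2 111 (22.7%), EMAIL3 36 (7.3%), PHONE 155 (31.6%)
personalization: OR 2.54 (95%CI 1.78-3.64), p = 0.000
outreach: OR 1.37 (95%CI 0.86-2.22), p = 0.190
six-month cumulative incidence, screened: 0.011 (95%CI 0.008-0.015; 3518 still at risk)
six-month cumulative incidence, detected: 0.031 (95%CI 0.017-0.044; 591 still at risk)
```

The simulated screened incidence sits on its 1% calibration anchor;
detection is more liberal than in the deployed system (the published
baseline survivor function was never released, so absolute risks — and
hence the detection rate at the 5% threshold — are baseline-dependent;
see `docs/methods.md`).

Other subcommands: `simulate` (cohort CSV only), `screen` and `alerts`
(stage-by-stage over a cohort CSV), `replicate` (distribution of
feasibility metrics over replicated studies). Every subcommand takes
`--config` and `--seed`; `run` writes a manifest with the config hash and
per-stage row counts alongside the report.

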