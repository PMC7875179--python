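# Full-scale replication of the deployment study conditions: a one-year
# intake window, n = 3722 screened-population marginals, ~35% predictor
# incompleteness at entry, outcomes generated from the published
# coefficients with the six-month incidence anchor, and the calibrated
# alert-response behaviour.  `psyscreen report --fixture published-funnel`
# swaps the simulation for the packaged funnel fixture.
study:
  start_date: "2018-01-01"
  end_date: "2018-12-31"
  threshold: 0.05
  horizon_days: 730
  min_age: 14
model:
  baseline: cohort   # published betas; score on the outcome-calibrated baseline
cohort:
  n_patients: 3722
  entry_start: "2018-01-01"
  entry_end: "2018-12-31"
  missing_fraction: 0.35
  weekly_completion_prob: 0.25
  followup_days: 730
  attrition_hazard: 0.00012
workflow:
  step_gap_weeks: 1
  personalization_effect: 2.35
  outreach_effect: 2.02
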