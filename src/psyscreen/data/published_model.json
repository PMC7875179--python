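{
 "betas": {
  "age": 0.01,
  "male": 0.457,
  "age_male": -0.009,
  "ethnicity.Black": 0.995,
  "ethnicity.Asian": 0.487,
  "ethnicity.Mixed": 0.686,
  "ethnicity.Other": 0.34,
  "diagnosis.Acute-transient-psychotic": 1.169,
  "diagnosis.Substance-use": -1.748,
  "diagnosis.Bipolar-mood": 0.003,
  "diagnosis.Non-bipolar-mood": -1.56,
  "diagnosis.Anxiety": -2.006,
  "diagnosis.Personality": -1.363,
  "diagnosis.Developmental": -3.337,
  "diagnosis.Childhood-adolescence-onset": -3.2,
  "diagnosis.Physiological-syndromes": -2.31,
  "diagnosis.Mental-retardation": -2.326
 },
 "baseline": {
  "form": "exponential",
  "rate": 0.00023806078424772704
 },
 "horizon_days": 730
}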