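# Default allometric-equation registry for synthetic surveys.
#
# SYNTHETIC: these coefficients are plausible literature-style values
# chosen for the simulated species pool (sp001 = production-forest
# conifer dominant, sp002 = exotic-woodland broadleaf dominant,
# sp003..sp005 = natural-forest endemic dominants); they are not
# transcribed measurements.  Real analyses should supply their own
# registry file in this format.  AGB output is kg dry mass; D in cm,
# H in m, BA in m2 per tree.
- taxon_id: generic
  form: power_d
  predictors: [D]
  coefficients: {a: 0.12, b: 2.4}
  source: "synthetic generic broadleaf power law"
- taxon_id: sp001
  form: power_d2h
  predictors: [D, H]
  coefficients: {a: 0.035, b: 0.96}
  source: "synthetic conifer volume-type equation"
- taxon_id: sp002
  form: loglinear_dh
  predictors: [D, H]
  coefficients: {a: -2.1, b: 2.2, c: 0.45}
  source: "synthetic broadleaf log-linear equation"
- taxon_id: sp003
  form: power_d
  predictors: [D]
  coefficients: {a: 0.15, b: 2.3}
  source: "synthetic endemic tree power law"
- taxon_id: sp004
  form: power_d
  predictors: [D]
  coefficients: {a: 0.13, b: 2.35}
  source: "synthetic endemic tree power law"
- taxon_id: sp005
  form: linear_ba
  predictors: [BA]
  coefficients: {a: 1.5, b: 520.0}
  source: "synthetic basal-area linear equation"
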