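# Default model parameters: English major-trauma triage cost-utility model.
# Costs in GBP (2017/18 prices). Survival-model coefficients are illustrative,
# TARN-like values (the published TARN 2006 coefficients are not redistributed);
# replace them via a user config for analyses against real data.
clinical:
  transfer:
    tp: 0.266   # ISS >= 16 & tool positive (stabilised locally, then transferred)
    fn: 0.325   # ISS >= 16 & tool negative
    tn: 0.043   # ISS < 16 & tool negative
    fp: 0.074   # ISS < 16 & tool positive
  effects:
    rr_death30_local_iss16: 1.25
    rr_death30_local_issLT16: 1.0
    p_death_30d_1yr_iss16: 0.036
    rr_1yr_local_iss16: 1.64
    p_death_30d_1yr_issLT16: 0.017
    hr_longterm_issLT16: 1.38
    hr_longterm_iss16: 5.19
    benefit_fraction_9to15: 0.0
    rr_death30_local_iss9to15: 1.0
    rr_1yr_local_iss9to15: 1.0
  survival_model:
    form: logit_linear
    coefficients:
      intercept: 1.70
      age: -0.035
      iss: -0.085
      gcs: 0.30
      male: -0.10
utility:
  u_iss9plus: 0.65
  ara_constant: 0.9508566
  ara_age: -0.0002587
  ara_age2: -0.0000332
  ara_male: 0.0212126
  ref_age: 61.0
  ref_male_prop: 0.591
cost:
  transfer_cost: 252.0
  mtc_admit_iss16: 2819.0
  mtc_admit_iss9to15: 1466.0
  blunt_treatment_bands:
    - {upper: 9, cost: 6198.0}
    - {upper: 16, cost: 8989.0}
    - {upper: 25, cost: 14205.0}
    - {upper: null, cost: 21173.0}
  penetrating_treatment_bands:
    - {upper: 9, cost: 6501.0}
    - {upper: 15, cost: 6035.0}
    - {upper: 24, cost: 9453.0}
    - {upper: 34, cost: 12347.0}
    - {upper: null, cost: 16438.0}
  post_discharge_6mo: 1766.0
  longterm_mult_iss16: 1.45
  longterm_mult_issLT16: 1.25
economics:
  discount_rate: 0.035
  maicers: [20000.0, 30000.0]
  horizon_age_cap: 100
tools:  # ordered from most specific to most sensitive
  - {label: "28.4% Sens, 88.6% Spec", sensitivity: 0.284, specificity: 0.886}
  - {label: "57.0% Sens, 80.0% Spec", sensitivity: 0.570, specificity: 0.800}
  - {label: "64.2% Sens, 76.1% Spec", sensitivity: 0.642, specificity: 0.761}
  - {label: "69.8% Sens, 70.1% Spec", sensitivity: 0.698, specificity: 0.701}
  - {label: "74.6% Sens, 65.7% Spec", sensitivity: 0.746, specificity: 0.657}
  - {label: "87.5% Sens, 62.8% Spec", sensitivity: 0.875, specificity: 0.628}
  - {label: "90.4% Sens, 58.4% Spec", sensitivity: 0.904, specificity: 0.584}
  - {label: "94.8% Sens, 18.7% Spec", sensitivity: 0.948, specificity: 0.187}
  - {label: "99.8% Sens, 2.5% Spec", sensitivity: 0.998, specificity: 0.025}
psa:
  default_se_frac: 0.2
  tool_ess_positive: 1000.0
  tool_ess_negative: 10000.0
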