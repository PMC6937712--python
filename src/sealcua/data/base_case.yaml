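label: base_case
model:
  baseline_age: 6.0
  cycle_length: 2.0
  n_cycles: 3
  discount_rate: 0.03
  discount_effects: true
  wtp_threshold: 29.36
  utility_weights:
    sound: 1.0
    sealed: 1.0
    filled: 0.81
    extracted_caries: 0.0
    extracted_other: 0.0
  currency:
    clp_per_usd: 681.09
    reference_date: '2019-05-07'
epidemiology:
  prevalence_trend:
    baseline_prevalence: 0.25
    increment_per_cycle: 0.103
    baseline_age: 6.0
    cycle_length: 2.0
  effectiveness:
  - years: 0.0
    effectiveness: 1.0
    ci_low: 1.0
    ci_high: 1.0
  - years: 2.0
    effectiveness: 0.78
    ci_low: 0.66
    ci_high: 0.85
  - years: 4.0
    effectiveness: 0.6
    ci_low: 0.49
    ci_high: 0.69
  - years: 6.0
    effectiveness: 0.48
    ci_low: 0.37
    ci_high: 0.57
  rates:
    reseal:
      base: 0.03
      low: 0.0
      high: 0.13
    refill:
      base: 0.01
      low: 0.0
      high: 0.14
    extraction_caries:
      base: 0.001
      low: 0.0008
      high: 0.0012
    extraction_other:
      base: 0.0001
      low: 8.0e-05
      high: 0.00012
costs:
  sealant:
    base: 5.406
    low: 4.682
    high: 6.396
  filling:
    base: 11.129
    low: 9.638000000000002
    high: 13.086
  extraction:
    base: 3.989
    low: 3.802
    high: 4.661
  molar_exam:
    base: 0.19179166666666667
    low: 0.16433333333333336
    high: 0.22875
distributions:
  prevalence_increment:
    family: normal
    mean: 0.103
    half_width: 0.02
  effectiveness:
    family: table
  reseal_rate:
    family: beta
    mean: 0.03
    low: 0.0
    high: 0.13
  refill_rate:
    family: beta
    mean: 0.01
    low: 0.0
    high: 0.14
  extraction_caries_rate:
    family: beta
    mean: 0.001
    low: 0.0008
    high: 0.0012
  extraction_other_rate:
    family: beta
    mean: 0.0001
    low: 8.0e-05
    high: 0.00012
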