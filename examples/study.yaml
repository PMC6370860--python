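simulate:
  n_individuals: 3000
  seed: 1
  variant_specs:
  - rsid: rs11591147
    gene: PCSK9
    maf: 0.014
    ldl_beta: -12.97
    annotation: missense
    imputation_r2: 0.95
    ld_block: rs11591147
  - rsid: rs639750
    gene: PCSK9
    maf: 0.327
    ldl_beta: -1.82
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs639750
  - rsid: rs533617
    gene: APOB
    maf: 0.038
    ldl_beta: -4.4
    annotation: missense
    imputation_r2: 0.92
    ld_block: rs533617
  - rsid: rs531819
    gene: APOB
    maf: 0.155
    ldl_beta: -4.07
    annotation: intron
    imputation_r2: 0.98
    ld_block: rs531819
  - rsid: rs1367117
    gene: APOB
    maf: 0.316
    ldl_beta: 3.52
    annotation: missense
    imputation_r2: 0.99
    ld_block: rs1367117
  - rsid: rs6511720
    gene: LDLR
    maf: 0.114
    ldl_beta: -5.79
    annotation: regulatory_intron
    imputation_r2: 0.97
    ld_block: rs6511720
  - rsid: rs6511721
    gene: LDLR
    maf: 0.483
    ldl_beta: 1.73
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs6511721
  - rsid: rs2738447
    gene: LDLR
    maf: 0.415
    ldl_beta: -1.67
    annotation: nmd_transcript
    imputation_r2: 0.98
    ld_block: rs2738447
  - rsid: rs72658867
    gene: LDLR
    maf: 0.011
    ldl_beta: -10.2
    annotation: splice_region
    imputation_r2: 0.85
    ld_block: rs72658867
  - rsid: rs5742911
    gene: LDLR
    maf: 0.307
    ldl_beta: -1.79
    annotation: three_prime_utr
    imputation_r2: 0.96
    ld_block: rs5742911
  - rsid: rs7000000
    gene: PCSK9
    maf: 0.08
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000000
  - rsid: rs7000001
    gene: APOB
    maf: 0.14
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000001
  - rsid: rs7000002
    gene: LDLR
    maf: 0.21
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000002
  - rsid: rs7000003
    gene: PCSK9
    maf: 0.27
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000003
  - rsid: rs7000004
    gene: APOB
    maf: 0.33
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000004
  - rsid: rs7000005
    gene: LDLR
    maf: 0.38
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000005
  - rsid: rs7000006
    gene: PCSK9
    maf: 0.44
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000006
  - rsid: rs7000007
    gene: APOB
    maf: 0.5
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000007
  - rsid: rs7000008
    gene: LDLR
    maf: 0.08
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000008
  - rsid: rs7000009
    gene: PCSK9
    maf: 0.14
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000009
  - rsid: rs7000010
    gene: APOB
    maf: 0.21
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000010
  - rsid: rs7000011
    gene: LDLR
    maf: 0.27
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000011
  - rsid: rs7000012
    gene: PCSK9
    maf: 0.33
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000012
  - rsid: rs7000013
    gene: APOB
    maf: 0.38
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000013
  - rsid: rs7000014
    gene: LDLR
    maf: 0.44
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000014
  - rsid: rs7000015
    gene: PCSK9
    maf: 0.5
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000015
  - rsid: rs7000016
    gene: APOB
    maf: 0.08
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000016
  - rsid: rs7000017
    gene: LDLR
    maf: 0.14
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000017
  - rsid: rs7000018
    gene: PCSK9
    maf: 0.21
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000018
  - rsid: rs7000019
    gene: APOB
    maf: 0.27
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000019
  - rsid: rs7000020
    gene: LDLR
    maf: 0.33
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000020
  - rsid: rs7000021
    gene: PCSK9
    maf: 0.38
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000021
  - rsid: rs7000022
    gene: APOB
    maf: 0.44
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000022
  - rsid: rs7000023
    gene: LDLR
    maf: 0.5
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000023
  - rsid: rs7000024
    gene: PCSK9
    maf: 0.08
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000024
  - rsid: rs7000025
    gene: APOB
    maf: 0.14
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000025
  - rsid: rs7000026
    gene: LDLR
    maf: 0.21
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000026
  - rsid: rs7000027
    gene: PCSK9
    maf: 0.27
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000027
  - rsid: rs7000028
    gene: APOB
    maf: 0.33
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000028
  - rsid: rs7000029
    gene: LDLR
    maf: 0.38
    ldl_beta: 0.0
    annotation: intron
    imputation_r2: 0.99
    ld_block: rs7000029
  ld_block_r2: {}
  phecode_specs:
  - phecode: 272.1
    prevalence: 0.3
    effects:
      rs11591147: 0.64
      rs531819: 0.88
      rs1367117: 1.07
      rs6511720: 0.83
      rs6511721: 1.07
    label: hyperlipidemia
    n_codes: 2
    exclusion_low: 272.0
    exclusion_high: 272.99
  - phecode: 272.11
    prevalence: 0.18
    effects:
      rs11591147: 0.6
      rs531819: 0.87
      rs6511720: 0.8
    label: hypercholesterolemia
    n_codes: 1
    exclusion_low: 272.0
    exclusion_high: 272.99
  - phecode: 367.1
    prevalence: 0.08
    effects:
      rs6511720: 0.85
    label: myopia
    n_codes: 2
    exclusion_low: 367.0
    exclusion_high: 367.99
  - phecode: 250.2
    prevalence: 0.12
    effects: {}
    label: type_2_diabetes
    n_codes: 2
    exclusion_low: 250.0
    exclusion_high: 250.99
  - phecode: 366.1
    prevalence: 0.1
    effects: {}
    label: cataract
    n_codes: 2
    exclusion_low: 366.0
    exclusion_high: 366.99
  - phecode: 411.1
    prevalence: 0.15
    effects:
      rs639750: 0.96
    label: ischemic_heart_disease
    n_codes: 2
    exclusion_low: 411.0
    exclusion_high: 411.99
  llm_probability: 0.237
  llm_reduction: 0.75
  n_related_pairs: 15
  sites:
  - - site_a
    - 0.4
  - - site_b
    - 0.35
  - - site_c
    - 0.25
  single_code_noise_rate: 0.05
  exclusion_code_rate: 0.02
  unmapped_code_rate: 0.01
  ldl_intercept: 130.0
  ldl_sd: 30.0
  ldl_meas_sd: 5.0
  measurements_range:
  - 1
  - 3
  birth_year_range:
  - 1920
  - 2000
  event_day_range:
  - 0
  - 4999
  female_fraction: 0.54
thresholds:
  ldl_p_max: 0.01
  min_cases: 50
mode: primary
crossval: true
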