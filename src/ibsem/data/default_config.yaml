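# ibsem configuration.
# Provenance: structural constants (21 loci with a neutral 21st, wild/farm/
# strayer allele frequencies 0.9/0.1/0.8, 5% straying, 90 mm smolting
# threshold with 50% probability at 103 mm, parr share Gaussian(0.30, 0.10),
# mate caps 2 adults + 5 parr, seasonal calendar, Table-style initial
# abundances and lengths) are reference-stated; every growth/mortality/
# maturation coefficient and the fecundity slope are outputs of the shipped
# calibration procedure (`ibsem calibrate`).
environment:
  river_area_m2: 250000.0
  river_temp_mean:
  - 3.0
  - 2.8
  - 3.9
  - 6.2
  - 9.4
  - 12.6
  - 15.0
  - 15.3
  - 12.6
  - 9.3
  - 6.1
  - 4.0
  river_temp_sd:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  sea_temp_mean:
  - 6.2
  - 5.8
  - 5.7
  - 6.3
  - 7.8
  - 9.9
  - 11.9
  - 12.6
  - 11.6
  - 9.9
  - 8.4
  - 7.1
  sea_temp_sd:
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  - 0.6
  randomize: true
genetics_decay: 0.3
wild_allele_freq: 0.9
farm_allele_freq: 0.1
rates:
  growth:
    condition_factor_juv: 1.05e-05
    condition_factor_adult: 1.22e-05
    allometric_b: 0.85
    t_min: 2.0
    t_max: 22.0
    ramp_parr:
    - 7.0
    - 12.0
    ramp_smolt:
    - 0.0
    - 10.0
    ramp_sea:
    - 4.0
    - 8.0
    a_parr:
    - 1.0991318638102803
    - 0.6404764539944824
    - 0.4102190763592532
    a_smolt: 0.3105167817066463
    l_inf_mm: 1100.0
    kappa_sea:
    - 0.04845821120445501
    - 0.0381671377375571
    - 0.05379212127092134
    - 0.11601112164820426
    density_coef: 0.5
    genotype_gain: 0.15
    noise_sd_parr: 0.3
    noise_sd_smolt: 0.2
    noise_sd_sea: 0.25
    alevin:
      intercept_mm: 10.959685860584445
      slope_mm_per_g: 120.0
      noise_sd_mm: 1.0
  mortality:
    egg_base: 0.88
    egg_size_slope: 1.0
    egg_density_coef: 0.122
    egg_genotype_gain: 0.2
    alevin_monthly: 0.03
    juv_warm:
    - 0.0
    - 0.005
    - 0.005
    juv_rest:
    - 0.03520373728267501
    - 0.022490595553935955
    - 0.0
    smolt_monthly: 0.030933550501910823
    juv_density_coef:
    - 0.45
    - 0.025
    - 0.025
    juv_genotype_gain: 0.03
    marine_m_inf: 0.002
    marine_amplitude: 0.2448143711728861
    marine_length_scale_mm: 250.0
    marine_genotype_gain: 0.04
    marine_age_mult:
    - 4.994353655132243
    - 1.0
    - 1.0
    - 1.0
    ed:
      gamma: 1.0
      w_ref_g: 2.9
  maturation:
    parr_midpoint_mm: 106.57023505965851
    parr_steepness_mm: 9.0
    repeat_multiplier: 2.0
    adult_base:
    - 0.5
    - 0.88
    - 1.0
    adult_genotype_gain: 0.35
  smolting:
    threshold_mm: 90.0
    midpoint_mm: 103.0
    steepness_mm: 3.0
  fitness_differential_scale: 1.0
spawning:
  fecundity_slope_per_g: 1.6
  fecundity_intercept: 0.0
  fecundity_sd_frac: 0.1
  egg_weight_intercept_g: 0.07
  egg_weight_slope_per_g: 4.0e-06
  egg_weight_sd_frac: 0.1
  egg_weight_min_g: 0.03
  max_adult_mates: 2
  max_parr_mates: 5
  parr_share_mean: 0.3
  parr_share_sd: 0.1
  parr_prespawn_mortality_range:
  - 0.2
  - 0.4
  adult_postspawn_mortality: 0.9
  escapee_success_factor: 0.33
straying:
  stray_fraction: 0.05
  incoming_wild_freq: 0.8
  mirror_mode: false
escapee:
  n_per_year: 0.0
  sea_age_probs:
  - 0.2
  - 0.6
  - 0.2
  length_mean_mm:
  - 590.0
  - 700.0
  - 840.0
  length_sd_frac: 0.05
  wild_allele_freq: 0.1
initial:
  n_p0: 600000.0
  n_p1: 30000.0
  n_p2: 30000.0
  n_smolt: 0.0
  n_adult: 1000.0
  len_p0_mm: 23.0
  len_p1_mm: 65.0
  len_p2_mm: 100.0
  len_adult_mm:
  - 140.0
  - 560.0
  - 670.0
  - 800.0
  len_sd_p0_mm: 1.0
  len_sd_parr_mm: 8.0
  len_sd_adult_frac: 0.05
tracked_loci:
- 1
- 2
- 5
- 10
- 20
- 21
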