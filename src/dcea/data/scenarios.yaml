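# Versioned presets for the synthetic external-input generator.  These tables
# stand in for inputs the analysis needs but whose sources are not publicly
# printed: all-cause mortality by age and deprivation quintile, smoking-status
# proportions, smoking-related disease incidence, baseline quality-adjusted
# life expectancy (QALE), health-opportunity-cost shares and the Atkinson
# inequality-aversion parameter.  All values are SYNTHETIC.
#
# Conventions: quintile vectors run IMD1 (most deprived) .. IMD5 (least).
# Mortality follows a Gompertz-like curve base_rate * exp(slope*(age-18))
# scaled by a quintile multiplier; disease incidence is per-disease
# exponential in age for smokers, with a former-smoker relative rate.

default:
  mortality:
    base_rate: 3.0e-4           # annual probability at age 18, IMD3
    slope: 0.085                # per year of age
    cap: 0.7                    # ceiling on any annual rate
    quintile_multipliers: [1.30, 1.15, 1.00, 0.90, 0.80]
  smoking_proportions:
    smoker_at_18: [0.19, 0.17, 0.15, 0.13, 0.12]
    smoker_age_decline: 0.0015  # absolute decline per year of age
    smoker_floor: 0.02
    former_at_18: 0.05
    former_age_rise: 0.004
    former_cap: 0.45
  disease_incidence:            # smokers; annual probability at age 18, slope/yr
    lung_cancer: {base: 2.0e-5, slope: 0.080}
    chd: {base: 1.0e-4, slope: 0.070}
    copd: {base: 8.0e-5, slope: 0.075}
    mi: {base: 8.0e-5, slope: 0.070}
    stroke: {base: 6.0e-5, slope: 0.075}
    asthma_exacerbation: {base: 5.0e-3, slope: 0.005}
    former_relative_rate: 0.5
    former_relative_rate_asthma: 0.8
    cap: 0.5
  baseline_qale: [62.0, 65.0, 68.0, 71.0, 74.0]     # QALYs per person
  opportunity_cost_shares: [0.30, 0.25, 0.20, 0.15, 0.10]
  inequality_aversion: 10.95
  jitter_sd: 0.05               # lognormal sd of seeded scale jitter

flat:                           # no quintile gradients anywhere (symmetry tests)
  mortality:
    base_rate: 3.0e-4
    slope: 0.085
    cap: 0.7
    quintile_multipliers: [1.0, 1.0, 1.0, 1.0, 1.0]
  smoking_proportions:
    smoker_at_18: [0.15, 0.15, 0.15, 0.15, 0.15]
    smoker_age_decline: 0.0015
    smoker_floor: 0.02
    former_at_18: 0.05
    former_age_rise: 0.004
    former_cap: 0.45
  disease_incidence:
    lung_cancer: {base: 2.0e-5, slope: 0.080}
    chd: {base: 1.0e-4, slope: 0.070}
    copd: {base: 8.0e-5, slope: 0.075}
    mi: {base: 8.0e-5, slope: 0.070}
    stroke: {base: 6.0e-5, slope: 0.075}
    asthma_exacerbation: {base: 5.0e-3, slope: 0.005}
    former_relative_rate: 0.5
    former_relative_rate_asthma: 0.8
    cap: 0.5
  baseline_qale: [68.0, 68.0, 68.0, 68.0, 68.0]
  opportunity_cost_shares: [0.2, 0.2, 0.2, 0.2, 0.2]
  inequality_aversion: 10.95
  jitter_sd: 0.0

steep-gradient:                 # exaggerated deprivation gradients
  mortality:
    base_rate: 3.0e-4
    slope: 0.085
    cap: 0.7
    quintile_multipliers: [1.60, 1.30, 1.00, 0.80, 0.65]
  smoking_proportions:
    smoker_at_18: [0.26, 0.20, 0.15, 0.11, 0.08]
    smoker_age_decline: 0.0015
    smoker_floor: 0.02
    former_at_18: 0.05
    former_age_rise: 0.004
    former_cap: 0.45
  disease_incidence:
    lung_cancer: {base: 2.0e-5, slope: 0.080}
    chd: {base: 1.0e-4, slope: 0.070}
    copd: {base: 8.0e-5, slope: 0.075}
    mi: {base: 8.0e-5, slope: 0.070}
    stroke: {base: 6.0e-5, slope: 0.075}
    asthma_exacerbation: {base: 5.0e-3, slope: 0.005}
    former_relative_rate: 0.5
    former_relative_rate_asthma: 0.8
    cap: 0.5
  baseline_qale: [56.0, 62.0, 68.0, 74.0, 80.0]
  opportunity_cost_shares: [0.40, 0.27, 0.17, 0.10, 0.06]
  inequality_aversion: 10.95
  jitter_sd: 0.05
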