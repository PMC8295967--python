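# National parameter book: printed distribution parameters for England plus
# synthetic stand-ins (provenance: synthetic) for inputs whose source tables
# are not publicly printed.  IMD1 = most deprived quintile, IMD5 = least.
region: england
population_size: 42994944          # all adults in England, ONS 2017 mid-year
quintile_shares: [0.2, 0.2, 0.2, 0.2, 0.2]
provenance:
  population_size: published
  quintile_shares: published

settings:
  discount_rate: 0.035             # per year, QALYs and costs
  background_quit_rate: 0.02      # natural annual quit probability
  threshold_k: 20000.0             # GBP per QALY
  age_cap: 100
  entry_age_min: 18
  entry_age_max: 75

entries:
  # Smoking prevalence, beta(alpha, beta) by quintile
  prevalence_imd1: {family: beta, params: {alpha: 2441.0, beta: 11775.0}, provenance: published, printed_mean_pct: 17.17}
  prevalence_imd2: {family: beta, params: {alpha: 1516.0, beta: 7984.0}, provenance: published, printed_mean_pct: 15.96}
  prevalence_imd3: {family: beta, params: {alpha: 887.0, beta: 5406.0}, provenance: published, printed_mean_pct: 14.09}
  prevalence_imd4: {family: beta, params: {alpha: 688.0, beta: 4733.0}, provenance: published, printed_mean_pct: 12.68}
  prevalence_imd5: {family: beta, params: {alpha: 601.0, beta: 4676.0}, provenance: published, printed_mean_pct: 11.38}

  # Relative risk of death, smokers v. nonsmokers by age band; lognormal(lm, lv)
  rr_death_svn_35_44: {family: lognormal, params: {lm: 0.63, lv: 0.17}, provenance: published, printed_point: 1.87}
  rr_death_svn_45_54: {family: lognormal, params: {lm: 0.82, lv: 0.11}, provenance: published, printed_point: 2.28}
  rr_death_svn_55_64: {family: lognormal, params: {lm: 0.68, lv: 0.09}, provenance: published, printed_point: 1.97}
  rr_death_svn_65_74: {family: lognormal, params: {lm: 0.61, lv: 0.08}, provenance: published, printed_point: 1.83}
  rr_death_svn_75plus: {family: lognormal, params: {lm: 0.31, lv: 0.08}, provenance: published, printed_point: 1.37}
  # Smokers v. former smokers, constant across ages
  rr_death_svf: {family: lognormal, params: {lm: 0.09, lv: 0.02}, provenance: published, printed_point: 1.11}

  # Relative risk of developing smoking-related disease by quintile (IMD5 reference)
  rr_disease_imd1: {family: lognormal, params: {lm: 0.137, lv: 0.041}, provenance: published, printed_point: 1.15}
  rr_disease_imd2: {family: lognormal, params: {lm: 0.109, lv: 0.039}, provenance: published, printed_point: 1.12}
  rr_disease_imd3: {family: lognormal, params: {lm: 0.114, lv: 0.038}, provenance: published, printed_point: 1.12}
  rr_disease_imd4: {family: lognormal, params: {lm: 0.079, lv: 0.039}, provenance: published, printed_point: 1.08}
  rr_disease_imd5: {family: fixed, params: {value: 1.0}, provenance: published}

  # Average 12-month quit rates of the interventions, beta(alpha, beta)
  quit_rate_varenicline: {family: beta, params: {alpha: 6.0, beta: 25.0}, provenance: published, printed_point: 0.19}
  quit_rate_ecigarette: {family: beta, params: {alpha: 13.0, beta: 87.0}, provenance: published, printed_point: 0.13}

  # Relative risk of quitting smoking by quintile (IMD1 reference, fixed)
  rr_quit_imd1: {family: fixed, params: {value: 1.0}, provenance: published}
  rr_quit_imd2: {family: lognormal, params: {lm: 0.297, lv: 0.168}, provenance: published, printed_point: 1.35}
  rr_quit_imd3: {family: lognormal, params: {lm: 0.195, lv: 0.201}, provenance: published, printed_point: 1.22}
  rr_quit_imd4: {family: lognormal, params: {lm: 0.236, lv: 0.154}, provenance: published, printed_point: 1.27}
  rr_quit_imd5: {family: lognormal, params: {lm: 0.308, lv: 0.168}, provenance: published, printed_point: 1.36}

  # Stop-smoking-service uptake rate by quintile, beta(alpha, beta)
  uptake_imd1: {family: beta, params: {alpha: 96.0, beta: 2284.0}, provenance: published, printed_mean_pct: 4.03}
  uptake_imd2: {family: beta, params: {alpha: 93.0, beta: 1349.0}, provenance: published, printed_mean_pct: 6.48}
  uptake_imd3: {family: beta, params: {alpha: 93.0, beta: 1316.0}, provenance: published, printed_mean_pct: 6.62}
  uptake_imd4: {family: beta, params: {alpha: 90.0, beta: 795.0}, provenance: published, printed_mean_pct: 10.14}
  uptake_imd5: {family: beta, params: {alpha: 90.0, beta: 817.0}, provenance: published, printed_mean_pct: 9.92}

# HRQoL linear-regression coefficients (EQ-5D utility scale).  Means are the
# published point estimates; the covariance is NOT published and is rebuilt at
# load time as D R D with se = max(0.10 |coef|, se_floor) and exchangeable
# correlation rho (synthetic stand-in for the extracted variance-covariance
# matrix; correlated draws still go through its Cholesky factor).
hrqol:
  coefficients:
    constant: 0.903
    age_25_34: -0.0124
    age_35_44: -0.0544
    age_45_54: -0.0681
    age_55_64: -0.0986
    age_65_74: -0.107
    age_75plus: -0.1630
    smoker: -0.0340
    imd2: 0.0320
    imd3: 0.0281
    imd4: 0.0545
    imd5: 0.0736
  se_fraction: 0.10
  se_floor: 0.005
  rho: 0.2
  provenance:
    means: published
    covariance: synthetic

# Stand-ins for the unpublished supplementary cost/disutility table.  Means
# are synthetic order-of-magnitude placeholders; distributions follow the
# stated rule (gamma, standard error = 10% of mean).
costs_and_disutilities:
  se_fraction: 0.10
  provenance: synthetic
  intervention_costs:            # GBP per treated smoker, first cycle
    varenicline: 320.0
    ecigarette: 65.0
  disease_costs:                 # GBP per disease event
    lung_cancer: 12000.0
    chd: 4000.0
    copd: 3000.0
    mi: 5000.0
    stroke: 10000.0
    asthma_exacerbation: 600.0
  disease_disutilities:          # absolute utility decrement per event
    lung_cancer: 0.15
    chd: 0.08
    copd: 0.10
    mi: 0.09
    stroke: 0.12
    asthma_exacerbation: 0.02
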