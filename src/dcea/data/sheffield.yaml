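# Local-authority overlay: Sheffield.  Same layout as york.yaml.  Sheffield
# has higher smoking prevalence and a population skewed toward the more
# deprived quintiles; shares are a synthetic preset (published source is a
# bar chart).
region: sheffield
population_size: 574000
quintile_shares: [0.30, 0.25, 0.20, 0.15, 0.10]
provenance:
  population_size: published
  quintile_shares: synthetic

prevalence:                            # mean %, 95% CI %
  imd1: {mean: 22.27, ci: [15.86, 28.68], provenance: published}
  imd2: {mean: 20.60, ci: [14.47, 26.72], provenance: published}
  imd3: {mean: 19.84, ci: [13.89, 25.79], provenance: published}
  imd4: {mean: 18.45, ci: [12.74, 24.16], provenance: published}
  imd5: {mean: 17.74, ci: [12.21, 23.28], provenance: published}
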