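# Local-authority overlay: York.  Smoking prevalence means and 95% CIs are the
# published local figures (converted to betas by moment matching at load
# time); every other uncertain input is inherited from the England book.
# Quintile population shares are a synthetic preset (the published source is a
# bar chart, not a table): York's population is skewed toward the less
# deprived quintiles.  The source text gives the population as both 205,000
# and 207,000; 207,000 is used here.
region: york
population_size: 207000
quintile_shares: [0.05, 0.10, 0.20, 0.30, 0.35]
provenance:
  population_size: published          # (205,000 also appears in the source)
  quintile_shares: synthetic

prevalence:                            # mean %, 95% CI %
  imd1: {mean: 16.91, ci: [11.86, 21.96], provenance: published}
  imd2: {mean: 14.56, ci: [9.95, 19.16], provenance: published}
  imd3: {mean: 13.57, ci: [9.19, 17.96], provenance: published}
  imd4: {mean: 11.64, ci: [7.62, 15.66], provenance: published}
  imd5: {mean: 10.78, ci: [6.95, 14.60], provenance: published}
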