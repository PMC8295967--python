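"""Build sampling distributions from a published parameter table.

Proportions with a mean and standard error become beta distributions by
moment matching; positive costs with "se = 10% of mean" become gammas; a
relative risk reported as a point with a 95% CI becomes a lognormal.  The
printed integer (alpha, beta) pairs of the national uptake table are
recovered exactly.
"""

import dcea

# Stop-smoking-service uptake, most deprived quintile: mean 4.03%, se 10% of mean
alpha, beta = dcea.beta_from_mean_se(0.0403, 0.00403)
print(f"uptake IMD1: Beta(alpha={alpha:.1f}, beta={beta:.1f}) "
      f"-> printed table rounds to ({round(alpha)}, {round(beta)})")

# A disease cost of 12,000 GBP with se = 10% of mean
shape, scale = dcea.gamma_from_mean_se(12_000.0, 1_200.0)
print(f"lung-cancer cost: Gamma(shape={shape:.0f}, scale={scale:.0f}) GBP")

# The packaged national book carries the printed parameters verbatim
book = dcea.fixture_parameter_book("england")
spec = book.entries["prevalence_imd1"]
s = dcea.distribution_summary(spec)
print(f"smoking prevalence IMD1: mean {100 * s.mean:.2f}%, "
      f"95% CI ({100 * s.quantile(0.025):.2f}%, {100 * s.quantile(0.975):.2f}%)")
# The mean and CI match the published table row for the most deprived quintile.
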