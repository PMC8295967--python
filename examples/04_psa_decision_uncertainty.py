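"""Probabilistic sensitivity analysis and decision probabilities.

Propagates parameter uncertainty through the model by Monte Carlo and
summarises decision uncertainty as the probability that each comparison
improves overall health (iNHB > 0) and reduces inequality (iEDE > iNHB).
A few hundred iterations are enough to see the pattern; analyses use 1,000.
"""

import dcea

book = dcea.fixture_parameter_book("england")
externals = dcea.generate_external_inputs(seed=0, scenario="default")

psa = dcea.run_psa(book, externals, n=300, seed=42)
print(dcea.psa_summary_table(psa).round(1).to_string())
print(f"\ntruncated draws: {psa.truncation_count} "
      f"(probabilities clipped to [0,1], relative risks to (0,inf))")
# Active arms v. none: certain health gain, certain inequality increase.
# Varenicline v. e-cigarette: genuine decision uncertainty on both axes —
# the case where value-of-information analysis earns its keep.

# scatter_frame(psa) exports (iteration, comparison, delta, inhb) rows for
# plotting the equity impact plane.
print(dcea.psa.scatter_frame(psa).head().to_string(index=False))
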