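"""Which uncertain inputs drive the decision uncertainty?

Two complementary attributions on the same PSA matrices: expected value of
(partial) perfect information, monetised at the threshold, and ANCOVA
variance shares from a main-effects linear model on the sampled inputs.
"""

import dcea

book = dcea.fixture_parameter_book("england")
externals = dcea.generate_external_inputs(seed=0, scenario="default")
psa = dcea.run_psa(book, externals, n=500, seed=42)

voi = dcea.voi_report(psa, comparison="varenicline_vs_ecigarette",
                      threshold_k=book.settings.threshold_k, seed=0)
health = voi[voi.framing == "health"].sort_values("value_gbp", ascending=False)
print("value of information, overall-health framing (GBP):")
print(health[["group", "value_gbp"]].to_string(index=False,
                                               float_format="{:,.0f}".format))
# EVPI is the value of resolving all uncertainty before choosing between the
# two active interventions; the per-group EVPPI shows the average quit rates
# dominate — collecting better effectiveness evidence is where value lies.

anc = dcea.ancova_report(psa)
cell = anc[(anc.output == "inhb") & (anc.comparison == "varenicline_vs_ecigarette")]
print("\nANCOVA shares of variance in iNHB (varenicline v. e-cigarette):")
print(cell[["group", "share"]].sort_values("share", ascending=False)
      .to_string(index=False, float_format="%.3f"))
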