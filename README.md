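# dcea — distributional cost-effectiveness analysis of smoking cessation

Cost-effectiveness analysis tells a health system whether an intervention
buys health at an acceptable price.  **Distributional** cost-effectiveness
analysis (DCEA) additionally tracks *who* gets that health: it stratifies a
decision model by socioeconomic group, follows both the direct health gains
and the health forgone elsewhere when spending is displaced, and summarises
the result on two axes — overall health impact and health-inequality impact.
This package implements a complete, tested DCEA pipeline for the canonical
worked problem in this literature: two smoking-cessation interventions
(varenicline and e-cigarettes) versus no intervention for adult smokers in
England, stratified by Index of Multiple Deprivation (IMD) quintile
(IMD1 = most deprived), with full uncertainty analysis.

It is a library for health economists and methods researchers: the public
face is the importable API plus `examples/` (one short narrative script per
capability), with a thin `dcea` command-line wrapper for batch runs.

## The model and metrics

**Cohort model.** A three-state annual-cycle Markov model (smoker, former
smoker, dead; no relapse) per quintile and arm.  Smokers quit with
probability `q · RR_quit(IMD)` — the intervention quit rate in the first
cycle of an active arm, the 2%/yr background rate thereafter.  Smoker
mortality is recovered from all-cause mortality `m` by inverting the
population mixture

```
m_s = m / (p_s + p_f / RR_svf + p_n / RR_svn),
```

with former-smoker and nonsmoker rates `m_s/RR_svf`, `m_s/RR_svn`.  Six
smoking-related diseases (lung cancer, CHD, COPD, MI, stroke, asthma
exacerbation) occur as independent events contributing one-cycle costs and
utility decrements; HRQoL comes from a linear regression on age band,
smoking status and IMD quintile.  QALYs and costs are discounted at 3.5%/yr.

**Equity metrics.** For a pairwise comparison, pooled incremental cost `C`
is converted to forgone health `C·s_q/k` (threshold `k` = £20,000/QALY,
opportunity-cost shares `s_q` falling more heavily on deprived quintiles),
giving per-quintile incremental net health benefit
`iNHB_q = ΔQALY_q − C·s_q/k`.  Adding `iNHB_q/N_q` to the baseline
quality-adjusted life expectancy `h_q` and applying the Atkinson
equally-distributed-equivalent

```
EDE_ε(h) = (Σ_q w_q h_q^(1−ε))^(1/(1−ε))      (ε ≠ 1)
```

yields the population incremental EDE; the **inequality impact** is
`iEDE − iNHB` (positive = inequality reducing).  Each comparison lands in a
quadrant of the *health equity impact plane*.

**Uncertainty machinery.** Monte Carlo PSA (beta/gamma/lognormal inputs,
HRQoL coefficients drawn via the Cholesky factor of their covariance,
per-iteration seed substreams → bitwise reproducible), decision
probabilities `P(iNHB>0)` and `P(iEDE>iNHB)`, expected value of perfect
information `EVPI = E[max_d payoff] − max_d E[payoff]` with regression-based
EVPPI (additive splines up to 4 parameters, Gaussian process beyond), and
ANCOVA sum-of-squares attribution of output variance to parameter groups.

Published inputs (the national distribution-parameter table and the local
prevalence tables for York and Sheffield) ship as packaged fixtures;
everything the analysis needs but the literature does not print — mortality
tables, disease incidence, baseline QALE, opportunity-cost shares, the
aversion parameter, the HRQoL covariance, local quintile shares, the
supplementary cost/disutility table — is generated by the synthetic-data
module and clearly flagged `synthetic`.  Headline numbers therefore match
the published analysis in structure and qualitative pattern, not digit for
digit.

## Worked example

```python
import dcea

book = dcea.fixture_parameter_book("england")          # printed parameters
externals = dcea.generate_external_inputs(seed=0)      # synthetic stand-ins

print(dcea.base_case(book, externals).round(0))
psa = dcea.run_psa(book, externals, n=300, seed=42)
print(dcea.decision_probabilities(psa).round(3))
```

prints (base case, then decision probabilities):

```
                              inhb     iede   delta
comparison
varenicline_vs_none        51385.0  42360.0 -9025.0
ecigarette_vs_none         35576.0  30598.0 -4978.0
varenicline_vs_ecigarette  15810.0  11762.0 -4048.0

                           p_inhb_positive  ...  p_inequality_reduced
varenicline_vs_none                  1.000  ...                 0.000
ecigarette_vs_none                   1.000  ...                 0.000
varenicline_vs_ecigarette            0.700  ...                 0.083
```

Reading: both interventions raise overall population health with certainty
(positive iNHB, probability 1.0) but widen the health gradient (negative
inequality impact, probability of reducing inequality 0) — the better-off
quit more successfully and take up services more.  Choosing *between* the
two active interventions is genuinely uncertain (P(iNHB>0) ≈ 0.70), which is
where the value-of-information analysis (`dcea.voi_report`) earns its keep:
it attributes essentially all of that decision uncertainty to the average
intervention quit rates.  See `examples/` for the full tour, and

```bash
dcea run --region england --n 1000 --seed 42 --out out/
```

for the batch bundle (inputs/outputs/summary/scatter/voi/ancova CSVs plus a
reproduction manifest).

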