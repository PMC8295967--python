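# Methods

This note documents the model, its numerical conventions, the synthetic
stand-ins, and the design choices that were genuinely open.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Cohort model

Three states (smoker, former smoker, dead), annual cycles, cohort entering
entirely as smokers.  The per-cycle order of operations is: accrue (events,
QALYs, costs, from start-of-cycle occupancy), then quit, then die.  The
discount factor for cycle *t* (t = 0, 1, …) is (1+r)^(−t) with r = 0.035/yr
for both QALYs and costs; there is no half-cycle correction.  Relapse is
zero: former-smoker occupancy falls only through death, which the test suite
asserts on randomised draws.

**Mortality.** Smoker mortality inverts the population mixture:
`m_s = m/(p_s + p_f/RR_svf + p_n/RR_svn)` with status-specific rates
`m_s/RR_svf`, `m_s/RR_svn`, so the proportion-weighted average reproduces the
all-cause rate exactly (a unit test asserts this identity).  This direction
makes smokers die *more* than average when the relative risks exceed one —
the only reading consistent with the published risk table.  The smoker-v-
nonsmoker relative risk is published for ages 35+ only; below 35 the model
uses RR_svn = 1 (no excess) while the age-constant smoker-v-former RR still
applies.  Status proportions enter as fixed external tables, not sampled;
parameter uncertainty flows through the relative risks only.

**Diseases.** Six smoking-related diseases are independent, memoryless
events: expected count = occupancy × incidence(age, status) × quintile RR.
The base incidence table is taken to represent the middle quintile (IMD3),
so quintile scaling uses RR_q / RR_IMD3 (both sampled); IMD3 reproduces the
base table draw by draw.  Each event contributes a one-cycle cost and an
absolute utility decrement; there is no prevalent-disease state.

**Entry ages and censoring.** Entrants are 18–75, uniform by default
(configurable weights); every cohort is censored at the age cap of 100
(no accrual at or beyond the cap).  Per-smoker outcomes are the entry-age-
weighted average of per-age totals; a vectorised multi-age engine computes
them, and the tests pin it to the scalar single-age reference
implementation at 1e-12.

**Population scaling.** Smokers in quintile q number N·w_q·π_q.  In an
active arm only the uptaking fraction u_q receives the intervention (and its
first-cycle unit cost); non-uptakers follow the no-intervention pathway.  So
an arm's quintile total is the uptake-weighted mix, and an active-vs-none
increment is (treated count) × (per-smoker difference).

## Equity metrics

Incremental costs are pooled across quintiles before conversion to forgone
health (funding displacement happens at the level of the total budget), then
distributed by the opportunity-cost shares s_q.  Per-quintile population
iNHB is diluted over the *whole* quintile population (h′_q = h_q +
iNHB_q/N_q) before the Atkinson EDE is applied; this makes the inequality
impact exactly zero at ε = 0, so iEDE − iNHB isolates pure inequality
change.  Dilution over smokers only is a documented alternative the
maintainer can add at the `EquitySettings` level; full-population dilution
is the default because baseline QALE is a whole-population quantity.

Numerical choices in `atkinson_ede`: ε = 0/1/2 use the mean, geometric and
power-mean forms directly; an exactly-equal distribution short-circuits to
the common level.  The short-circuit matters: population scaling multiplies
EDE by N ≈ 4.3×10⁷, which would amplify ~1e−13 relative power-mean rounding
to ~1e−5 absolute and mask the flat-scenario symmetry the tests assert at
1e−6.  Quadrant labels on the equity plane: win/lose by the signs of iNHB
and iEDE−iNHB, with exact zeros labelled "boundary".

## Uncertain inputs

Distribution families follow health-economics convention: beta for
proportions (moment-matched when only mean and SE are known: ν =
m(1−m)/se² − 1), gamma for costs and disutilities (shape = (m/se)², scale =
se²/m; the "se = 10% of mean" rule gives shape 100), lognormal (lm, lv) for
relative risks, multivariate normal via Cholesky for the HRQoL regression
coefficients.  Reference categories (RR of quitting in IMD1, RR of disease
in IMD5) are fixed at 1 and never sampled.  After transformation, sampled
probabilities are truncated to [0,1] and relative risks to (0,∞); truncation
events are counted and reported in the PSA metadata and run manifest.
Sampling order is sorted-by-name, so a book's insertion order cannot change
results.

The published parameter table prints both means and (α, β) pairs that are
mutually inconsistent in the second decimal for some rows; the fixtures
store the printed (α, β)/(lm, lv) verbatim and the tests compare against the
printed means with tolerances that absorb that internal rounding.

## Synthetic stand-ins

The analysis needs several inputs its source literature does not print.
`generate_external_inputs(seed, scenario)` produces deterministic synthetic
versions, all flagged `synthetic`:

* **All-cause mortality**: Gompertz-like, 3×10⁻⁴·exp(0.085·(age−18)) at
  IMD3, quintile multipliers 1.30…0.80 (IMD1…IMD5), capped at 0.7/yr.
* **Smoking-status proportions**: prevalence-like smoker share declining
  with age, former-smoker share rising, remainder never-smokers.
* **Disease incidence**: per-disease exponential age curves for smokers;
  former smokers at half the rate (asthma 0.8).
* **Baseline QALE** h_q = (62, 65, 68, 71, 74) QALYs, IMD1→IMD5.
* **Opportunity-cost shares** s_q = (0.30, 0.25, 0.20, 0.15, 0.10).
* **Inequality aversion** ε = 10.95 (a placeholder; always overridable, and
  a sweep over ε ∈ {0, 1, 2, 5, 10.95, 20} is built in).
* **HRQoL covariance**: D·R·D with se = max(0.10·|coef|, 0.005) and
  exchangeable correlation ρ = 0.2 — synthetic in scale but preserving the
  correlated-draw mechanism.
* **Local quintile population shares** for York (skewed less-deprived) and
  Sheffield (skewed more-deprived), and the supplementary cost/disutility
  means, are order-of-magnitude presets flagged `synthetic` in the YAML.

The seed perturbs only scale factors (lognormal jitter, sd 0.05), so age
monotonicity and gradient orderings hold for every seed.  The `flat`
scenario removes every quintile gradient; paired with `flatten_book` (which
pins quintile-specific book quantities to a common fixed value and zeroes
the IMD utility coefficients) it gives the end-to-end symmetry the tests
assert: no gradients ⇒ inequality impact 0 (±1e−6 at population scale).
Flattening the book as well as the externals is necessary — independent
per-quintile draws of uptake or prevalence would otherwise leave a residual
inequality impact of order 0.1 QALYs per iteration.

**What passing tests therefore show** is that the machinery is correct —
conservation, monotonicity, symmetry, closed forms, reproducibility — on
data with the right shape.  They do not show that the synthetic tables
match England: the published headline figures depend on unpublished
mortality, incidence, QALE, opportunity-cost and aversion inputs, so this
pipeline reproduces their structure and qualitative pattern (certain health
gain, certain inequality increase versus no intervention; genuine
uncertainty between the two active interventions; quit-rate uncertainty
dominant), not their exact values.

## PSA, VOI, ANCOVA

PSA uses one root `SeedSequence` spawning a substream per iteration: results
are bitwise reproducible for (seed, n) and would be invariant to worker
parallelisation.  All three arms share each iteration's sample (common
random numbers), so within-iteration increments are exact differences.
n defaults to 1,000; probabilities are printed to two decimals.

VOI frames each pairwise comparison as two decisions with payoffs
{0, iNHB·k} (health) or {0, (iEDE−iNHB)·k} (equity) — the payoff builder is
exposed and swappable.  EVPI is the standard estimator; EVPPI regresses each
decision's payoff on the parameter subset: additive cubic splines (6 knots)
for ≤ 4 columns, a subsampled (≤ 400 points) anisotropic-RBF Gaussian
process with nugget for more.  GP lengthscales are bounded below (0.5 on
standardised inputs) and initialised long, so an uninformative subset yields
a flat fit and near-zero EVPPI rather than interpolation noise.  Estimates
are clipped at 0 and capped at EVPI in reports; the reported SE is the Monte
Carlo error of the fitted regret, a heuristic that ignores regression
uncertainty.

ANCOVA standardises inputs, fits one main-effects OLS on all grouped
columns, and attributes explained sum of squares by drop-one-group ΔSS
(marginal, type-III-like; a sequential mode exists for comparison).  With
independently sampled inputs the attributions nearly coincide; chance sample
correlation can push the share sum a little past 1, which is logged beyond
1.02 and rejected as collinearity beyond 1.25.  Parameter groups mirror the
conventional sensitivity axis: prevalence, RR of death, RR of disease, HRQoL
coefficients, average quit rates, RR of quitting by IMD, uptake by IMD,
costs, disutilities.

## Problem sizes and defaults

Defaults are the study conditions: 1,000 PSA iterations, population
42,994,944 (England; York 207,000, Sheffield 574,000), threshold £20,000/
QALY, discount 3.5%, background quit 2%/yr, entry ages 18–75, age cap 100.
Oracle and property tests run at the sizes their closed forms need (10⁵
draws for the normal-EVPI check, 5,000 for the ANCOVA toy, 200 iterations
for the flat-scenario sweep), chosen so each check resolves its tolerance
comfortably.

## Known limitations

No relapse, no prevalent-disease states, no sex stratification, no
correlation between quintiles within an input (independent draws are a
second-best the source analysis also accepts), intervention effects confined
to the first cycle, and a synthetic externals layer that is plausible rather
than estimated.  EVPPI standard errors are heuristic.  Scatter export is
CSV only; plotting is left to the user.
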