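# Methods

This note documents the statistical procedures implemented in `lifemeth`,
the design choices made where several reasonable options existed, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Lifestyle index

Each of the four factors maps to points 0/1/2, lowest points for the
highest disease risk:

| factor | 0 points | 1 point | 2 points |
|---|---|---|---|
| smoking | current | former | never |
| alcohol | > 1♀ / > 2♂ units/day | > 0 and ≤ 1♀ / ≤ 2♂ | abstainer (0 units) |
| physical activity | IPAQ low | IPAQ moderate | IPAQ high |
| diet | DQI-I ≤ 33.33 | 33.33 < DQI-I ≤ 66.66 | DQI-I > 66.66 |

The total ∈ [0, 8] is an unweighted sum; totals in [0, 4] are classed
high-risk (binary index 1), totals in (4, 8] low-risk. The boundary value
4 is deliberately high-risk.

Conventions worth making explicit:

- **IPAQ day-slot summation.** The "7 or more days of any combination"
  and "5 or more days of any combination" clauses are operationalized as
  `vigorous_days + moderate_days + walking_days ≥ 7` (resp. 5). Day slots
  may double-count a calendar day on which two activity types occurred;
  this is IPAQ's own scoring convention, adopted here as a documented
  choice. The "high" rules are evaluated before "moderate".
- **DQI-I tertiles** are fixed thirds of the 0–100 range, not empirical
  tertiles of the sample.
- **Missing lifestyle values are rejected** (complete-case): imputation
  belongs upstream of this package.

## DMP discovery

Testing happens on M-values, M = log2(b/(1−b)) with β clipped to
[ε, 1−ε], ε = 10⁻⁶ by default; effect sizes are reported on the β scale
as the high-minus-low-risk group difference. The per-probe model is OLS
of M on intercept, binary index, age, sex, one-hot site/batch/array-
position indicators (first level dropped) and estimated cell proportions
(first dropped — they sum to one); the secondary model adds BMI. The fit
is fully vectorized: with H = (XᵀX)⁻¹Xᵀ shared across probes, all
coefficients come from one matrix product, so results are exactly
invariant to probe order.

**Variance moderation.** Per-probe residual variances s² are modelled as
s² | σ² ~ σ²·χ²_d/d with a scaled inverse-χ²(d₀, s₀²) prior. (d₀, s₀²)
are estimated by method of moments on log s² (digamma/trigamma
identities; the trigamma equation is solved by Newton iteration). The
posterior variance s̃² = (d₀s₀² + d·s²)/(d₀ + d) yields a moderated t
with d + d₀ degrees of freedom. When the variances are essentially
identical the prior degrees of freedom are infinite and s̃² = s₀² — the
documented full-shrinkage limit.

**Empirical-null correction.** Moderated t statistics are mapped to
signed z-scores through their two-sided p-values, and a three-component
normal mixture is fitted by EM: a central component for the (possibly
biased and inflated) null bulk and two flanking components for true
signal. Two constraints keep the estimator honest on signal-free input,
where unconstrained mixture likelihoods reward letting a "tail" eat the
centre: tail means must sit at least three null-SDs from the central
mean, and tail SDs are bounded below by the null SD. A weak Dirichlet
prior (pseudo-counts 20/2/2) stabilizes the weight updates.
Initialization is deterministic (median/MAD, tails at ±3 MAD, weights
0.9/0.05/0.05), convergence is declared at a relative log-likelihood
change below 10⁻⁶ (cap 1000 iterations), and a non-converged fit falls
back to median/MAD with a warning. Corrected statistics are
z′ = (z − μ̂)/σ̂; two-sided p-values from z′ are then BH-adjusted, with
FDR < 0.05 the genome-wide significance threshold. On signal-free grids
the estimator recovers σ to within 0.5%; under simulated bias 0.5 and
inflation 1.5 it recovers both within the tested 5% bands.

The estimator needs ≥ 1000 probes — below that the mixture is not
meaningfully identified, and array-scale inputs always satisfy it.

## DMR discovery

1. **Clustering**: probes sorted by (chromosome, position); consecutive
   probes join a cluster iff the gap is ≤ `max_gap` (default 500 bp, the
   usual bump-hunting convention; exposed as a flag).
2. **Effects**: per-probe β-scale exposure coefficients from the same
   covariate-adjusted design as the DMP stage, so the candidate cutoff
   0.01 literally means a 1% methylation difference.
3. **Smoothing**: centred running mean (default window 5 probes)
   truncated at cluster edges; clusters of fewer than 3 probes pass
   through unsmoothed.
4. **Candidates**: maximal same-sign runs with |smoothed effect| >
   cutoff and ≥ 3 CpGs (the 3-CpG floor is enforced in the configuration
   and cannot be lowered). Area = Σ|smoothed effect|; the reported
   effect is the mean raw β-difference over the run.
5. **FWER**: the exposure column is permuted B times (default 500) with
   covariates fixed, the full smooth-and-call pipeline re-run, and the
   maximum null area recorded; fwer = (1 + #{null max ≥ area})/(1 + B).
   The add-one estimator avoids zero p-values; permuting only the
   exposure is an exchangeability-based approximate null given
   covariates, chosen over a residual bootstrap for simplicity and
   exactness under the no-association hypothesis. Calibration measured
   on signal-free simulations: a FWER < 0.05 region appears in ~5–8% of
   runs (50 seeds, B = 200), consistent with the nominal 5%.

## Outcome associations

T2DM: logistic regression (IRLS as implemented in statsmodels), odds
ratios with Wald 95% intervals (symmetric on the log scale). FBG and
HbA1c: OLS with t-intervals. Methylation predictors support two scalings,
both recorded rather than silently merged: β × 100 ("per 1% methylation
increase", the default for effect reporting) and the Blom rank-based
inverse-normal transform Φ⁻¹((r − 3/8)/(n + ¼)) (the default where
p-values against a skewed predictor matter). The adjusted model controls
for age, sex, site and BMI — the epidemiological covariate set, without
the EWAS technical covariates. Region-level association uses the mean β
across the region's probes. Perfect separation and non-convergence raise
typed errors rather than returning unstable estimates. No multiplicity
correction is applied across this small candidate set; p-values are
nominal.

## Mediation

Paths from three regressions: a from mediator ~ exposure (+covariates,
OLS), b and the direct effect from outcome ~ exposure + mediator, the
total effect from outcome ~ exposure. Binary outcomes use logistic
models, so b and the direct effect are log-odds coefficients and the
product a·b is scale-hybrid — a unit-change approximation, flagged here
because the total = direct + indirect identity holds (and is tested, to
10⁻⁸) only in the all-linear case. The indirect-effect distribution comes
from a percentile bootstrap over participants (default 1000 resamples;
BCa was not used because the percentile interval matches the plain
bootstrap description being reproduced). Replicates whose fits fail are
dropped and counted; more than 10% failures aborts the analysis. The
two-sided p-value is the add-one-adjusted fraction of replicates crossing
zero.

## Synthetic-data generator

The generator defines the study conditions; its defaults emulate the
published cohort rather than a convenient test case:

- n = 713 participants (426 in the acceptance runs, the discovery-set
  size); smoking never/former/current = 0.886/0.091/0.022; alcohol
  abstainer/moderate/heavy = 0.616/0.355/0.029; activity
  high/moderate/low = 0.417/0.229/0.355; DQI-I ~ N(56, 6.1²) truncated
  to [0, 100]; age ~ N(52, 10²); 42.6% male; BMI ~ N(27, 5.5²); site
  frequencies 0.146/0.341/0.513 (rural Ghana/urban Ghana/Europe).
  Published frequencies are rounded, so category vectors may sum to
  0.99–1.01 and are renormalized.
- Activity records are drawn so that IPAQ categorization round-trips:
  each sampled category generates a record that classifies back to it.
- β values: each probe has a baseline from an equal-weight two-component
  Beta mixture (Beta(2,10) and Beta(10,2)) — the standard bimodal array
  profile — and samples draw from a Beta law around that baseline with
  concentration κ = 100 (per-probe SD ≈ 0.02–0.05). Spiked probes shift
  the high-risk group's baseline by ±Δβ (default 0.02, the published
  effect scale of 1–2%); spiked baselines are kept mid-range so the
  shift survives clipping to [10⁻⁶, 1−10⁻⁶]. Spiked regions tighten the
  position gaps of a run of consecutive probes (default 10 probes,
  Δβ = 0.075 — the published bump magnitude) so they cluster at
  bump-hunting scale.
- Outcomes: T2DM from a logistic model on the binary index and the
  centred mean β of spiked probes (baseline prevalence ≈ 40%, index
  log-OR 0.25); FBG and HbA1c linear with Gaussian noise (SD 1.5 mmol/L
  and 10 mmol/mol), with methylation coefficients at the published
  per-1% effect scale (0.29 mmol/L and −2.9 mmol/mol per 1%).
- Cell proportions are a 6-component Dirichlet draw with whole-blood
  means (granulocytes ≈ 55%); batch (4 levels) and array position
  (8 levels) are categorical technical covariates.
- One integer seed drives three deterministically spawned sub-streams
  (participants / methylation / outcomes), so every artefact is
  reproducible from the seed alone.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: probe-type (Type I/II) chemistry and its
β distortion, genetic (mQTL) structure, correlated neighbouring probes
outside spiked regions, batch effects that actually influence β, missing
data, and population stratification. Calibration results (uniform null
p-values, nominal FWER) hold under the generator's independence
assumptions; real arrays violate them in ways the empirical-null step
only partially absorbs.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately chosen scales: null calibration
at 10,000 probes × 400 samples over 20 seeds; DMR calibration at 2,000
probes × 200 samples over 50 seeds with B = 200; power checks at n = 400
with Δβ = 0.05 (probes) and 0.08 (regions); mediation coverage at n = 300
with 200 bootstrap resamples over 50 seeds. These sizes put Monte-Carlo
error well inside the asserted bands while keeping the default test run
fast.

Ties in BH ranking are handled by stable sorting; q-values are the
running minimum of p·m/rank from the largest rank down, clipped to 1.
Degenerate inputs are first-class: constant probes give zero
coefficients, zero-variance columns make correlations NaN (flagged, not
zero), empty candidate lists skip permutation entirely, and an empty
p-value vector returns an empty q-vector.

## Known limitations

- The empirical-null EM assumes a normal null bulk; heavy-tailed
  residual distributions (extreme-baseline probes after logit transform)
  leave the far tail slightly liberal even when the bulk is perfectly
  calibrated. Inflation estimates on pure-null input carry a ≲ 1%
  downward bias from residual tail leakage.
- Permutation FWER treats covariates as fixed; with strong
  exposure–covariate correlation the null is approximate.
- The scale-hybrid indirect effect for binary outcomes is not a
  counterfactual natural indirect effect; no exposure–mediator
  interaction is modelled.
- No probe QC (detection p-values, cross-reactive probe lists) and no
  sex-chromosome special-casing: inputs are assumed already cleaned.
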