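# lifemeth

Epigenome-wide analysis of a **comprehensive lifestyle index (CLI)** on
Illumina 450k-style DNA methylation data, with downstream association and
mediation analysis for type 2 diabetes (T2DM) and glycaemic markers.

The package is aimed at epidemiologists and epigeneticists who want a
tested, reproducible implementation of the full analysis chain behind
lifestyle-EWAS studies — from raw lifestyle questionnaire variables to
differentially methylated positions (DMPs) and regions (DMRs), their
associations with disease outcomes, and causal mediation — together with a
synthetic-data generator that makes every stage testable against known
ground truth without access to restricted cohort data.

## What it computes

**Lifestyle index.** Four modifiable risk factors are each scored 0/1/2
(0 = highest risk): smoking status (current/former/never), alcohol intake
against the ESC cut-offs (≤1 unit/day for women, ≤2 for men; abstainers
score 2), IPAQ physical-activity category (low/moderate/high from
MET-minutes/week), and diet quality (DQI-I 0–100 in fixed thirds). The CLI
is the unweighted sum ∈ [0, 8]; a total ≤ 4 defines the binary high-risk
index used as the EWAS exposure.

**DMPs.** Per-probe linear models of M-values, M = log2(β/(1−β)), on the
binary index with adjustment for age, sex, site, estimated cell
proportions and technical covariates (optionally BMI). Residual variances
are shrunk by empirical-Bayes moderation (scaled inverse-χ² prior fitted
by method of moments), the resulting statistics are corrected for bias and
inflation with an empirical-null normal-mixture fit, and significance is
controlled by Benjamini–Hochberg FDR < 0.05. Effect sizes are reported as
Δβ (group difference of methylation fractions).

**DMRs.** Bump hunting: probes are clustered (same chromosome, gap ≤ 500
bp), covariate-adjusted β-scale effects are smoothed by a running mean,
candidate regions are same-sign runs above a 1% β-difference cutoff with
≥ 3 CpGs, and the familywise error rate comes from re-running the pipeline
under permutations of the exposure labels (default B = 500).

**Associations.** Each top DMP (per 1% methylation increase, or
inverse-normal transformed), the CLI and its component scores are related
to T2DM by logistic regression (odds ratios, Wald 95% CI) and to fasting
blood glucose (mmol/L) and HbA1c (mmol/mol) by linear regression, in
unadjusted and age/sex/site/BMI-adjusted models.

**Mediation.** Product-of-coefficients decomposition of the CLI → T2DM
effect through DMP methylation (path a: index → mean β; path b: β → T2DM
log-odds, exposure-adjusted; indirect effect a·b), with percentile
confidence intervals from 1000 participant-level bootstrap resamples.

## Worked example

```python
from lifemeth import SimulationConfig, simulate_bundle, run_dmp_ewas
from lifemeth.dmr import DMRParams, run_dmr_ewas
from lifemeth.mediation import run_mediation, path_diagram

cfg = SimulationConfig(n_samples=426, n_probes=20000, seed=1)
pheno, meth, truth = simulate_bundle(cfg)

dmp = run_dmp_ewas(meth, pheno)
print(dmp.head(3)[["probe_id", "chromosome", "delta_beta", "fdr"]])

dmrs = run_dmr_ewas(meth, pheno, DMRParams(seed=1))
med = run_mediation(pheno, meth, dmp["probe_id"].head(6).tolist(),
                    n_boot=1000, seed=1)
print(path_diagram(med[-1]))
```

This simulates a 426-participant cohort (category frequencies matching the
emulated study population: 88.6% never smokers, 61.6% abstainers, DQI-I
56 ± 6.1) with 20 spiked CLI-linked probes (Δβ = 0.02) and one spiked
10-probe region (Δβ = 0.075), then recovers them:

```
  probe_id chromosome  delta_beta          fdr
cg00003482      chr12    0.085338 1.373895e-38
cg00003487      chr12    0.078276 1.325441e-32
cg00003481      chr12    0.073631 7.366155e-29
```

13 probes reach FDR < 0.05 and the empirical-null fit reports essentially
no bias or inflation (μ = −0.014, σ = 1.000). The spiked region is called
as `chr12:3111734-3113031, n=10, avg Δβ=0.076, FWER=0.0020` — the average
β-difference matches the configured 0.075 spike. The mediation summary for
the mean of the top six DMPs:

```
  exposure -> mediator (a):      +0.07796
  mediator -> outcome (b):       -1.257
  indirect effect (a*b):         -0.09803
  95% bootstrap CI (indirect):   [-0.8927, 0.714]
  p (indirect, 1000 replicates): 0.837
```

The interval covers zero: in this generating model the lifestyle–T2DM link
is not routed through methylation strongly enough to detect at n = 426,
which is the expected behaviour (the indirect path exists but is weak).

## Command line

```bash
lifemeth simulate --n-samples 426 --n-probes 20000 --seed 1 --out data/
lifemeth score     --phenotype data/phenotype.tsv --out scores.tsv
lifemeth ewas-dmp  --phenotype data/phenotype.tsv --beta data/beta_matrix.tsv \
                   --annotation data/annotation.csv --model base --out dmp.tsv
lifemeth ewas-dmr  --phenotype data/phenotype.tsv --beta data/beta_matrix.tsv \
                   --annotation data/annotation.csv --permutations 500 --out dmr.tsv
lifemeth run       --config pipeline.yaml        # all stages in order
```

Inputs are plain text: phenotype TSV, probes × samples β-matrix TSV and an
Illumina-manifest-style annotation CSV (probe id, chromosome, 1-based
position, gene, feature). DMRs are additionally written as BED6 (0-based,
half-open).

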