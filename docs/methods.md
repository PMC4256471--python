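# Methods

## Association scans

Every SNP–probe pair is tested by ordinary least squares of expression
on allele dosage plus an intercept and a shared covariate matrix (e.g.
expression PCs). For speed both the expression matrix and the dosage
matrix are residualized against `[1, covariates]` once (QR-based
projection); per-pair simple regression on the residuals then yields
the same slope, standard error and t statistic as the full model
(Frisch–Waugh–Lovell), with the degrees of freedom of the full model,
n − k − 2 for k covariates. Two-sided P-values come from the t
distribution; underflow is floored at the smallest positive float and
should be read as an upper bound. When dosages or expression contain
missing values the scan falls back to per-pair complete-case OLS with
identical semantics.

Pair eligibility uses 1-based inclusive coordinates (BED inputs are
shifted at the I/O boundary). The SNP–probe distance is zero when the
SNP lies inside the probe interval and otherwise the distance to the
nearest probe end — the probe is an interval, not a point, and the
window rule is stated SNP-to-probe. Cis pairs: same chromosome and
distance < 1 Mb (configurable). Trans pairs: different chromosomes, or
distance > 10 Mb. Pairs in the 1–10 Mb gap are deliberately tested by
neither scan.

FDR is controlled per scan (cis and trans separately) by the
Benjamini–Hochberg step-up rule; the reported cutoff is the largest
p(k) ≤ k·fdr/m, with an explicit no-discoveries sentinel. Lead signals
are formed per probe by greedy clumping: seed at the smallest P (ties:
larger |β|, then smaller position — the tie-break is a determinism
choice, not a scientific one), absorb records within 5 Mb on the same
chromosome, repeat. Covariates that are themselves under genetic
control can absorb real trans signals, so
`filter_covariates_by_genotype` drops any covariate with a SNP
association P below 5×10⁻⁸ (marginal, correlation-based). The source
description of this filter is ambiguous about the inequality's
direction; we implement "no SNP association stronger than 5×10⁻⁸
survives", the reading under which genetically driven components are
removed.

## Mediation

For a trans signal (lead SNP G, trans transcript T) and candidate
mediator M, three OLS fits share one covariate set (the trans-scan
covariates; using the same set in all three models is a consistency
choice — the mediator model's covariates are otherwise unspecified):

1. T ~ G + C → β_unadj (total effect)
2. T ~ G + M + C → β_adj (direct effect), β₁ = the M coefficient
3. M ~ G + C → β₂

Mediation proportion: (β_unadj − β_adj)/β_unadj; with a single mediator
and shared covariates the OLS identity β₁β₂ = β_unadj − β_adj holds
exactly, so the difference and product-of-coefficients formulations
agree. A zero total effect makes the proportion undefined; it is
emitted as NaN with a warning, never dropped silently. The Sobel
statistic uses the first-order pooled SE
√(β₁²·var(β₂) + β₂²·var(β₁)); the Aroian variant (+ var₁·var₂) is an
option and is always slightly more conservative. The indirect-effect
P is two-sided normal.

Mediator selection mirrors eQTL practice: among cis probes within 1 Mb
of the lead trans-eSNP whose cis association passes the cis threshold,
the probe whose lead cis-eSNP has the highest LD r² (squared dosage
correlation in the analysis sample) with the lead trans-eSNP is
chosen; absence of a candidate is a value, not an error.
`multi_mediator_adjust` fits a single joint regression of the trans
transcript on the SNP plus all candidate cis transcripts, greedily
pruning collinear probes, for the case where a trans effect runs
through several local transcripts.

Classification: *mediated* iff proportion > 0 and Sobel P < cutoff.
The default cutoff is 10⁻⁵ (the screening rule for cohort-scale
results); the simulation suites can also be read at the nominal 0.05
level — see "Wrong mediator" below for when this matters.

## Structural simulators

All transcripts are built to be marginally standard normal: each
structural term is added and the residual noise variance is chosen so
the total variance is 1, so every effect is in SD units and parameters
are comparable across scenarios. (The alternative — applying β to an
unstandardized upstream variable — would make the nominal β drift away
from the realized slope as upstream terms accumulate.) Genotypes are
sums of two haplotypes under Hardy–Weinberg equilibrium. A pair of loci
with target LD r² is drawn from the two-locus haplotype distribution
with D = d_sign·√(r²·p_a q_a p_b q_b); the haplotype-frequency bounds
give the feasibility limit, and infeasible requests fail with the
maximum attainable r² in the message. Defaults: causal-variant
MAF 0.3 (a typical common variant; the source study used one real,
unnamed variant), sample size 1,799 (the cohort size), 500 replicates
per scenario cell.

**Measurement error.** M = b·(G − 2p) + ε with b²·var(G) = R²_cis
(default 0.1); T = β·M + ε_T (default β = 0.2). The measured mediator
is M plus Gaussian noise calibrated so corr(true, measured)² equals
r2_measure on the grid {1.00, 0.75, 0.50, 0.25, 0.10}; an optional
second knob applies the same to T (default noise-free, since mediator
error is what drives the attenuation of interest). A tag variant with
configurable LD to the causal one is emitted for analysis.

**Confounding.** U ~ N(0,1) loads on both the mediator (β_U-cis) and
the trans transcript (β_U-trans), with |β_U-trans| = |β_U-cis| and
free signs. The generating model is complete mediation; adjusting for
the confounded mediator (a collider on G → M ← U → T) biases the
direct effect by −β_U-cis·β_U-trans·cov(G,M)/(var(G)(1 − R²_cis)), so
sign(estimated proportion − 1) = sign(β_U-cis·β_U-trans), invariant to
allele recoding (both the total effect and the bias flip together).
The SNP is coded cis-increasing by default; the flipped coding is
exposed for sign experiments.

**Wrong mediator.** Two causal variants in LD drive the true mediator
(gene_m) and the transcript the analyst selects (gene_s); the trans
transcript depends on gene_m only. Scenario variants add (i) nothing
(LD only), (ii) a shared confounder of gene_m and gene_s with signed
per-transcript loadings (0.3/0.5 for weak/strong, mixed signs for
"negative confounding"), (iii) a directed effect ±0.25 between the two
transcripts in either direction, or (iv) a confounder of gene_s and the
trans transcript. Mediation is always run with gene_s at the causal
trans variant — the analysis an unlucky analyst would perform.

**Planted study.** `simulate_study` lays variants and probes on a
configurable multi-chromosome grid, plants cis effects (variance
fraction R²), mediated trans effects (through a planted cis probe) and
direct trans effects, and emits genotype/expression matrices plus a
truth table; everything round-trips through the TSV/BED writers.

## Grid summaries and the proportion's heavy tail

Per grid cell the drivers simulate n_reps replicates, run the
three-regression procedure at the analyst-facing variant/transcript,
and summarize with medians and quantiles (2.5/25/75/97.5%), the median
−log₁₀ Sobel P, and the fraction classified mediated. Medians, not
means: the proportion is a ratio whose denominator β_unadj sits only
~2.7 standard errors from zero at the default effect sizes
(R²_cis·β² ≈ 0.004 of the trans variance at n = 1,799), so the
estimator has Cauchy-like tails — individual replicates above 1 or
below 0 are routine and the replicate mean does not settle. The median
is stable (≈ 1.00 under the error-free baseline) and is what the
acceptance script reports. Conditioning on a significant total effect
would stabilize a mean but biases it downward (≈ 0.92 in the baseline)
through selection.

For *between-cell* comparisons (e.g. verifying that attenuation is
monotone along a grid) the drivers offer common random numbers: every
cell reuses the same per-replicate seeds, leaving each cell's marginal
distribution untouched while strongly correlating cells, a standard
paired variance-reduction design. Adjacent LD cells differ by only
~0.2 in median −log₁₀ Sobel P, below independent-seed noise at a few
hundred replicates.

At the default effect sizes the wrong-mediator scenarios produce a
population Sobel z of ≈ 2 (the indirect path through gene_s is capped
by β·c_s·c_m ≈ 0.2·0.25), so "evidence of mediation" there is a
nominal-0.05 phenomenon; the strict 10⁻⁵ screening cut essentially
never fires under those conditions, which is itself informative about
what the screening rule does and does not admit.

## Enrichment

`fisher_enrichment` is an exact two-sided hypergeometric test (via
scipy) with the cross-product odds ratio; a zero cell triggers a
flagged Haldane–Anscombe 0.5 correction of the OR only.
`matched_resampling_enrichment` bins the non-target pool into MAF
deciles × TSS-distance deciles (quantile edges computed on the pool;
boundary values go to the lower bin; tied edges collapse with a log
message), assigns targets with the same edges, and per replicate draws
— without replacement, per joint bin — as many pool SNPs as there are
targets, preserving the targets' joint histogram exactly. The
empirical P is the add-one estimator (1 + #{replicates ≥ observed}) /
(n_reps + 1), bounded below by 1/(n_reps+1). A target-occupied bin
with too few pool SNPs is a hard error naming the bin.

## What the simulators do not capture

Real haplotype-block structure, population stratification, imputation
uncertainty, probe cross-hybridization and batch effects are all out of
scope; genotypes are exchangeable HWE draws and transcripts Gaussian.
Passing tests therefore demonstrate the statistical machinery —
estimator behaviour under measurement error, confounding and wrong
selection — not robustness to those data artefacts. Cohort-scale
empirical results (counts of signals, enrichment P-values in real data)
require the original data and are not reproduced here.

## Numerical notes

Seeds: every generator takes an explicit seed; replicate r of a
scenario uses `default_rng([seed, r])`, so cells and replicates are
independent streams and byte-reproducible. P-values are floored at the
smallest positive double. Rank deficiency (including a mediator exactly
collinear with the SNP) raises rather than silently pseudo-inverting.
Problem sizes used by the test suite — 200 replicates per scenario
cell, a 50×20×10 oracle toy, a 200×60×30 null study, 2,000-replicate
Sobel null — are the package's default verification sizes and keep the
whole suite under a few minutes on one core.
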