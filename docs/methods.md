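# Methods

This note documents the statistical models, defaults, and design choices in
`cortwas`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort

**Genotypes.** Each locus holds `n_variants_per_locus` variants 2 kb apart;
loci are laid out 2.5 Mb apart cycling over 22 autosomes so that ± 500 kb
cis-windows never overlap. Two haplotypes per individual follow a first-order
Markov "mosaic": the allele at variant *j* copies variant *j−1* with
probability `ld_decay` and is otherwise drawn fresh at that variant's target
frequency (uniform on `maf_range`). On this construction the adjacent-variant
*dosage* correlation equals the decay constant and decays geometrically with
distance — an AR(1) correlation structure on exactly the scale the downstream
mathematics consumes (the LD matrix Λ). A latent-Gaussian copula thresholded
to dosages was considered and rejected: thresholding attenuates the
correlation (the phi coefficient is systematically below the latent
correlation), so the generator's one parameter would not mean what it says.

**Expression.** One gene per locus. `n_causal_eqtl` causal variants are drawn
inside the window; the genetic component g = Zβ is rescaled so its sample
variance is exactly `h2_cis`, then *shared across all tissues of the same
individual*. Tissue values are y = g + `diagnosis_effect`·diag + ε with
ε ~ N(0, 1−h²). Tissue membership is an independent Bernoulli per tissue with
the default probabilities (0.609, 0.314, 0.063, 0.052, 0.043, 0.043 for
DLPFC/TCX/FP/IFG/STG/PHG), reproducing a 790-individual, ~888-sample
repeated-measure design; individuals left out of every tissue are assigned
one at random. Covariates (age, sex, PMI, batch) are generated with zero
effect by default so type-I behavior of the normalization loop is testable;
`covariate_effects` injects real confounding when a test needs it.

**GWAS.** Summary statistics are generated analytically at the z level:
z = √N·Λα + MVN(0, Λ) per locus, with α = γ·β/σ_trait the SNP-level mediated
effect (γ = `mediation_effect`) on the standardized-genotype,
standardized-trait scale, and se = 1/√N. This matches the summary-statistic
contract of the association stage exactly and avoids simulating an
individual-level case-control GWAS; a test verifies the shortcut against an
explicit individual-level regression (|Δz| < 0.15 at N = 5000). The
distribution of trait effect sizes at real loci is unknown, so γ is a free
parameter rather than a calibrated quantity. Default GWAS N is 63,926.

**What it does not emulate:** admixture beyond discrete clusters, sex
chromosomes, imputation error, non-Gaussian expression noise, trans effects,
cell-type composition. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to those
real-data features.

## Genotype QC

Dosages count the .bim A1 (effect) allele; missing calls are NaN and are
mean-imputed *only* for PCA and GRM construction, never for weight training
(training windows are taken from the complete-case pipeline panel).
Coordinates are 1-based inclusive. LD pruning is a greedy left-to-right scan:
a variant is kept only if r² ≤ 0.2 with every kept variant within 50 kb, the
earlier variant winning ties — the dense limit of the windowed step
procedure, chosen because it guarantees the pairwise property for every
retained pair. Clustering uses deterministic k-means (fixed seed, k-means++)
on the PCs explaining > 1% of variance, k = 8 by default; k is exposed
because nothing in the decision surface pins it down.

## Normalization

The covariate loop summarizes each candidate's per-gene significance by the
*median* p-value across genes and regresses out, jointly with everything
already selected, all candidates with median p < 0.05, repeating on residuals
(max 10 rounds). The joint refit on the original values keeps residuals
exactly orthogonal to every regressed covariate. Diagnosis is regressed
unconditionally. Scaling uses the sample sd (n−1) so that a scaled row
round-trips exactly; zero-variance genes are dropped and logged.

## cis-heritability

y ~ N(0, σ²g·K + σ²e·I), K = ZZ′/m on column-standardized dosages. The total
variance is profiled out analytically and h² = σ²g/(σ²g+σ²e) maximized by
bounded Brent search on [0, 1−10⁻⁶] over the eigen-spectrum of K; with raw
genotypes supplied the spectrum comes from a thin SVD of Z (O(nm²)), which is
what makes thousand-gene calibration runs cheap. Because σ²g = 0 sits on the
boundary, the LRT p-value uses the 50:50 χ²₀:χ²₁ mixture; simulation confirms
P(p < 0.01) ≈ 0.01 under the null. The gate threshold is p < 0.01. The window
default is TSS ± 500 kb (a 1 Mb window centered on the TSS); the flank is a
parameter for users who want ± 1 Mb.

## Weight training

Folds are assigned to individuals (greedy bin-packing, descending sample
count, seeded tie order, always into the currently smallest fold), so no
individual's samples ever straddle a train/test split; fold sizes stay within
5% whenever n/k ≥ 20. Models: `top1` (marginal OLS slope of the best
marginal eQTL, ties to the lower index), `blup`
(w = (X′X + m(1−h²)/h² I)⁻¹X′y), `lasso` and `enet` (coordinate descent,
mixing 0.5, 15 log-spaced penalties spanning [λmax, 0.01·λmax], λ chosen by
the same group-aware folds). k = 5. CV R² is the squared correlation of
assembled out-of-fold predictions with y; its p-value uses the number of
*individuals* as effective n, since samples within an individual share the
genetic component and would otherwise pseudo-replicate. The best model is
refit on all data; genes whose best CV R² is not positive are dropped (they
would impute a zero-variance component). BSLMM is not in the default set
(MCMC-scale cost); the model list is a registry, so a sparse-Bayes
approximation can be plugged in.

## Association

Weights are stored on the standardized-genotype scale with the allele pair,
so harmonization is exact: GWAS z/β are negated when the alleles are swapped
relative to the panel (directly or after strand complement); strand-ambiguous
A/T and C/G SNPs are dropped. The gene statistic is z = w′z/√(w′Vw) with
V ← 0.95·V + 0.05·I — shrinkage that regularizes the quadratic form against
reference-panel sampling noise. BH-FDR supports an explicit comparison count
m ≥ #tests for conventions that correct over all matched comparisons.
Validation against observed expression uses Kendall tau-b. GWAS p-value
binning assigns each SNP once, precedence weighted > unweighted > intergenic
(an overlap rule the decision surface leaves open), and the rank-sum tests
are one-sided (lower p in the weighted bin) because the enrichment claim is
directional.

## Locus refinement

Loci are connected components of significant genes with overlapping
cis-windows. JCP forward selection adds, at each step, the gene with the
largest |conditional z| given the selected set (conditioning on Ω, the
predicted-expression correlation matrix w′Vw normalized), as long as BH over
the remaining conditional tests keeps at least one gene significant; ties
break on gene id. Selected genes get multivariate joint z-scores
(Ω⁻¹z scaled by the diagonal of Ω⁻¹) and the label *joint*; the rest get
conditional z and *marginal*, demoted to *dropped* when BH over the final
JCP p-values loses them. Near-collinear genes (conditional variance ≤ 10⁻⁸)
are flagged marginal with p = 1. This stopping rule is pinned by the
synthetic classification tests rather than inherited from any external
implementation.

SMR uses the training-set top eQTL (the top1-model SNP) as instrument;
T = z²e·z²g/(z²e+z²g) with a χ²₁ reference. Note the χ²₁ calibration holds in
the strong-instrument regime (|z_e| large, trait null) — under a global null
with both z's standard normal the statistic is bounded by each component and
the test is conservative; the Monte-Carlo check conditions on a strong
instrument accordingly, which is the only regime in which SMR is run (genes
with significant eQTLs). COLOC uses Wakefield log-ABFs with prior effect-size
variances 0.2² (case-control trait, log-odds scale) and 0.15² (expression)
and priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ — the standard single-causal-variant
defaults, stated here because they matter and are otherwise invisible.

## Gene-set expansion

The sparse regression inside the bootstrap is pluggable; the default selects
a support by elastic net (penalty 0.1·λmax, support capped at n/3) and
converts OLS-refit t-statistics to partial correlations r = t/√(t²+df) — a
statistic that is estimator-agnostic, which is the point: downstream only the
mean partial correlation across bootstraps and tissues is consumed.
Bootstraps resample *individuals* with replacement, carrying all their
samples. Inclusion cutoffs are SD multipliers of the mean-partial-correlation
vector (default 1.3, with an elbow diagnostic emitted since the appropriate
multiplier is set-specific); the cis co-regulation check adds window
neighbors with mean r > 0.1 to the seed set. Network expansion counts, over
deduplicated undirected edges touching the seed set, how many such edges each
outside gene sits on: broad = more than once, narrow = more than twice, both
intersected with the expressed-gene universe. Enrichment uses the two-sided
exact binomial with n = |set ∩ universe| (the universe-intersected count, so
that p0 and n refer to the same population) and OR = observed/expected
overlap percentage.

## Pipeline

Stages run in method order, each writing a manifest (parameters, SHA-256 of
inputs, row counts); an unchanged manifest lets a stage skip, making runs
resumable and hash-stable, and no stage mutates another's outputs. All
randomness flows from the single config seed. The report emits the gene table
sorted by q, QQ coordinates (expected vs observed −log10 p), the locus
classification table, and the median-χ² genomic inflation λ.

## Problem sizes in the calibration suites

The test and acceptance suites run the full method on simulated cohorts of
1000 genes (null calibration: 500 individuals, 8 variants/locus) and 50 genes
per h² level at 800 individuals (parameter recovery); fold-balance checks use
the full 790-individual/~888-sample replica, and JCP/COLOC classification
checks use 100 generative draws each. These sizes give the stated tolerances
(gate rate ±1%, mean ĥ² ±0.05, CV R² ±0.07, ≥90% classification) comfortable
Monte-Carlo margins while keeping a full run in minutes on one core.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multi-signal); no
HEIDI heterogeneity test; no kinship/relatedness QC; dense LD matrices per
locus (fine for cis windows, not genome-wide); the iterative normalization
loop tests covariates marginally, so heavily collinear covariate blocks enter
in the order their median p-values reach significance.
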