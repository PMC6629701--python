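# Methods

This note documents the statistical procedures twaskit implements, the
choices made where several reasonable options existed, and what the
synthetic-data experiments do and do not demonstrate.

## Expression model training (`cistrain`)

Per gene, candidate predictors are the variants on the gene's chromosome
with position in `[start − w, end + w]` (both bounds inclusive; default
w = 500,000 bp) whose imputation INFO r² strictly exceeds 0.8. The
response is the gene's measured expression; no covariates enter training.

The fit is an elastic net at mixing parameter α = 0.5 over a log-spaced
grid of 100 penalties (scikit-learn's path machinery, coordinate-descent
tolerance 1e-7). Predictors are standardized internally for the path fit;
reported weights are rescaled back to the raw dosage scale so they can be
applied directly to cohort dosages, with the intercept adjusted
accordingly. Zero-variance predictor columns are dropped before fitting.

Penalty selection minimizes the mean cross-validated squared error.
Cross-validation is leave-one-out by default; 10-fold (seeded, shuffled) is
available and is what the scaled-down end-to-end study uses, since the two
schemes select essentially the same models at these sizes and k-fold is an
order of magnitude cheaper at n = 500. Ties in the minimum CV error are
broken toward the smallest penalty — a deterministic rule that favors the
less-shrunk fit among equals. Note the penalty parameterization follows
scikit-learn, which differs from glmnet's by a scaling convention; since
the selection criterion is the CV error minimum over a dense grid, the
selected model is insensitive to the convention.

`cv_r2` is the squared Pearson correlation between the cross-validated
predictions at the selected penalty and the observed expression (an
alternative, 1 − MSE/Var, is easy to derive from the same predictions; the
squared correlation is the reported default). Genes whose selected fit
retains no variant, or whose expression is constant, produce no model.

Out-of-sample evaluation z-standardizes observed and imputed vectors per
gene before computing MSE, and uses Spearman's rho for the correlation;
genes with (numerically) constant predictions are flagged and excluded from
summary means. Model-set comparisons are paired two-sided t-tests on
per-gene differences; an all-zero difference vector is reported as
degenerate with p = 1.

## Harmonized imputation (`imputex`)

A model variant (effect, other) is matched against a cohort (ref, alt)
coding in a fixed order: indel check, strand-ambiguity check (A/T and C/G
pairs are dropped regardless of the cohort coding, since strand cannot be
resolved without frequencies), then direct / swapped / strand-flipped /
strand-flipped-swapped; anything irreconcilable is missing. Swapped
matches use dosage 2 − d. Missing or dropped variants are omitted from the
prediction — equivalent to assuming zero effect-allele dosage — and a gene
whose variants are all unusable is excluded and logged. An imputed matrix
is therefore an affine function of the available dosages, bit-invariant to
any combination of ref/alt swaps and strand flips of non-ambiguous
variants, and independent of variant order. Mean-dosage substitution for
missing variants was considered and not implemented: omission matches the
reference behavior this module reproduces and keeps the affine invariance
exact.

## Association testing (`twasassoc`)

Subject QC retains subjects within k SD (default 5) of the mean of each of
the first n PCs (default 2), with means and SDs computed once on the input
set. Logistic fits use Newton/IRLS maximum likelihood (statsmodels), with a
convergence tolerance of 1e-8 and at most 25 iterations; separation —
detected as non-convergence, diverging coefficients (|β| > 30 on imputed
expression scales) or a degenerate standard error — is reported as a
non-converged result with no finite estimate rather than a spurious number.
Rank-deficient designs raise an error naming the collinear columns.

Tiers use the Bonferroni threshold 0.05/n_genes for significance and one
order of magnitude higher for suggestive hits. Inflation uses the
median-χ² convention λ_GC = median(χ²₁(p)) / 0.4549364 and the
case-control rescaling λ_1000 = 1 + (λ_GC − 1)(1/n_ca + 1/n_co)/(2/1000).

Conditional analysis refits the logistic model with lead-variant dosages as
extra covariates. A lead absent from the panel is replaced by its
highest-r² proxy above 0.8 (ties broken by position), and the resolved set
is greedily pruned to pairwise r² < 0.2 before fitting. Mediation reports
100 · (1 − β_adjusted/β_marginal) from the mutually adjusted model, with a
seeded percentile bootstrap over subjects for the CI (the proportion is not
truncated, but values outside [0, 100] — and the collinear-mediator cap at
100 — are flagged). Replication requires direction consistency plus
p < 0.05 (nominal) or p < 0.05/n_tested (Bonferroni). Meta-analysis is
standard inverse-variance fixed effects; heterogeneity statistics are out
of scope.

## Germline-somatic interaction (`somatic`)

The fusion decision boundary is the expression value where a univariate
logistic fit of fusion status on partner expression crosses probability
0.5 (−b₀/b₁). The fit must discriminate: a non-positive or statistically
negligible slope (Wald z < 2), or a crossing outside the observed
expression range, raises an error; perfectly separated groups skip the
diverging MLE and return the gap midpoint, flagged. A fixed threshold
(e.g. the literature value 10.65 RPKM for ERG) can be supplied to bypass
fitting. Exclusion removes positives strictly below and negatives strictly
above the threshold and is idempotent.

Correlations: the Pearson path reports the least-squares slope test p, a
Fisher-z 95% CI, and a Shapiro-Wilk test on the regression residuals
(regression-based CIs would be the alternative; Fisher-z is the documented
choice). The Spearman path, for limited sample sizes, reports a seeded
percentile bootstrap CI over subject pairs (default 10,000 resamples).

## Regulatory mechanism (`regmech`)

TFBS evidence is tiered 1-4: prostate-line ChIP-Seq, prostate-line
DNase footprint motifs, non-prostate ChIP-Seq, and non-prostate footprints
or pure PWM predictions; per-variant and per-gene summaries take the
minimum (best) category, with LD proxies at r² ≥ 0.8 allowed to carry
evidence to a modeled eQTL (the inclusive bound is used consistently).
Enrichment against background genes combines a two-sided Fisher exact test
with a bootstrap odds-ratio distribution: each group's evidence count is
resampled with replacement (equivalently, binomially) for 10,000 seeded
iterations, zero cells receive a Haldane 0.5 correction, and the median and
2.5/97.5 percentiles are reported.

The allele-specific binding score is Σ_m rank_m^{−1/2}(log₁₀ p_{m,A1} −
log₁₀ p_{m,A2}) over the supplied binding matrices; because stronger
binding means a more negative log₁₀ p, a negative score favors allele A1.
Only the sign feeds the concordance count, which is tested with the exact
two-sided binomial (minimum-likelihood convention; at p₀ = 0.5 this
coincides with tail doubling). Variant positions are 1-based and peak
intervals BED-style 0-based half-open; the conversion happens exactly once,
at the overlap query, and the tally comparison against a seeded null
variant sample reports both Mann-Whitney and Welch t statistics, since
either may be wanted and neither is privileged. Virtual-4C coverage asks
whether the furthest-upstream and furthest-downstream modeled eQTLs fall
inside the maximal contiguous run of positive-density bins containing the
anchor bin.

## Synthetic data (`synthdata`)

The generator emulates the statistical structure the pipeline assumes,
not human genetics in detail. Genes are laid out round-robin across 22
autosomes, 2 Mb apart, with their cis variants within ±250 kb. Haplotypes
come from a Gaussian block copula: within blocks of `ld_block_size`
consecutive variants the latent normals share a factor with loading
√0.8, across blocks they are independent; per-variant MAF is uniform on
`maf_range` (default 0.05-0.5). Variant properties depend only on the
seed, so panels drawn with different `cohort` numbers are independent
subject samples from the same population — the mechanism by which training
panels and discovery cohorts share variants without sharing subjects.

Expression is √h² · z_genetic + √(1−h²) · ε with the genetic value built
from `n_causal_eqtls_per_gene` N(0,1)-weighted dosages and standardized
in-panel, so the genetic variance fraction equals `expression_h2` exactly
at the edges and in expectation elsewhere. Disease status follows
logit P = intercept(prevalence) + Σ log-OR · z_gene + covariate terms, with
the intercept solved by bisection; covariates are two standard-normal PCs,
age ~ N(60, 8) and BMI ~ N(27, 4) with zero default effects. The default
population prevalence is 0.5 so that case-control draws of equal size can
be sampled efficiently from desk-scale populations; this is a synthetic
design convenience — the association machinery never uses prevalence.
Tumor cohorts set partner expression to baseline + shift +
2(ρ·z + √(1−ρ²)ε) in fusion-positives (within-stratum correlation exactly
ρ) and baseline + 2ε in negatives. Regulatory annotations give genes of
interest category-1 evidence at odds `tfbs_enrichment_or` times a 0.3
background rate, and binding profiles agree with the expression-raising
allele with probability `binding_concordance`.

Every generator is a pure function of (config, seed); per-stage substreams
are derived deterministically, so identical configs give bit-identical
outputs. What passing tests on these data show: the estimators recover
their configured effects at the stated sampling precision, the tests are
calibrated under the null, and the plumbing (harmonization, thresholds,
bookkeeping) is exact. What they do not show: robustness to realistic LD
maps, population stratification beyond simple PC confounding, imputation
error, or expression normalization artifacts — real-data behavior is out
of this package's demonstrable scope.

## Scaled-down validation studies (`workflows`)

The end-to-end power study trains 200 gene models on 500 subjects
(h² = 0.5, 10-fold CV), imputes into an independently drawn population of
12,500, samples 5,000 cases and 5,000 controls, and scans; the same cohort
sizes are rescanned with all risk effects zeroed to measure null λ_1000.
These sizes keep the full study within a few minutes on one CPU while
leaving the power and calibration questions intact.

The mediation study draws, per replicate, a mediator M, gene
X = ρM + √(1−ρ²)ε (ρ = 0.5), and status from
logit = 0.15·X + 0.30·M on 6,000 subjects, so the configured mediated
proportion 100(1 − a/(a + bρ)) = 50%. Effects are deliberately small and
the sample large: logistic non-collapsibility attenuates the marginal
log-odds of a misspecified marginal model, and with larger coefficients
that attenuation (plus finite-sample ratio bias) would shift the estimand
visibly below the configured value. At these settings the mean recovered
proportion is within half a point of 50% and the percentile bootstrap CI
(200 resamples per replicate) covers it at close to its nominal rate.

The somatic stratification study simulates 200 small tumor cohorts
(n = 400, fusion fraction 0.4, within-positive correlation 0.3) and
records the positive-stratum rejection rate, the negative-stratum
rejection rate at α = 0.05, and the negative-stratum CI coverage of zero.

## Known limitations

* The elastic-net penalty grid and parameterization follow scikit-learn;
  weight sets are reproducible within this package but not numerically
  identical to other implementations at the same nominal settings.
* Imputation is individual-level only; summary-statistic TWAS and
  reference-LD machinery are out of scope.
* The VCF reader handles the DS-dosage subset this package writes; general
  VCF feature parsing is not attempted (dosage TSV is the primary format).
* Binding-affinity p-values and matrix ranks are consumed as inputs; the
  package does not compute affinities from position weight matrices.
* Sex chromosomes, relatedness inference, and genotype phasing/imputation
  are out of scope.
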