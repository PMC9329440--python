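# Methods

## The analysis

The package treats a *PRS pair comparison* as a fixed pipeline: two scoring
files are QC'd and harmonized against one dosage panel, each individual gets
two scores, and agreement between the scores is summarized at the population
level (correlation, AUC difference, NRI) and at the individual level
(percentile cross-classification, top-k% concordance, odds ratios by risk
bin). The pipeline is deterministic given its inputs and a seed; every
artifact (QC report, per-individual score tables, overlap listing, rendered
cross-table, JSON report) is written to the output directory.

### Scoring

`PRS_j = Σ_i β_i · d_ij` over the variants retained after QC, where `d_ij`
is the expected effect-allele count in [0, 2]. Panel dosages count copies of
the panel's `allele1`; when the published effect allele is the panel's
`allele2`, harmonization marks the variant and the engine uses `2 − d`.
This is mathematically identical to negating the weight (up to a constant
per individual, which standardization removes); complementing the dosage was
chosen so published weights are never rewritten. Scores are standardized to
mean 0, population SD 1 (divisor N) in the analysis population.

### Percentiles and risk bins

Percentile ranks use `100·(rank − 0.5)/N` with average ranks on ties — the
symmetric convention, chosen so the "top 1%" bin holds the expected `N/100`
individuals and so that all-tied input degenerates to percentile 50 rather
than 0 or 100. The seven bins (<1, 1–20, 20–40, 40–60, 60–80, 80–99, ≥99)
are half-open `[lo, hi)` with the top bin closed above. Percentiles are
ranked in the full analysis population (not among controls). Higher score is
assumed to mean higher risk for both scores; no automatic sign alignment is
attempted.

### Variant and sample QC

Defaults: remove palindromic (A/T, C/G) variants only when MAF > 0.49
(the verbatim rule — moderate-frequency palindromic variants are kept),
remove MAF < 0.005, keep only info score strictly > 0.4. MAF is always the
folded frequency computed from the target panel's dosages, post sample QC —
the paper trail for published analyses rarely states whether target or
reference frequencies were used, and target dosages are the only frequencies
guaranteed to be available. Strand flips are resolved by base complement for
non-palindromic pairs only; allele pairs matching in no orientation are
dropped as mismatches. Sample QC removes any individual carrying an upstream
exclusion flag (sex discordance, 3rd-degree relatedness, heterozygosity or
missingness outlier); the flags are consumed, never derived from genotypes.

### LD-proxy overlap

A score-A variant counts as represented in score B if it matches directly
(by variant id, falling back to chromosome:position when ids differ — both
keys are supported because published scores are inconsistent about them) or
if some B variant on the same chromosome within ±500 kb has dosage-scale
R² strictly above 0.8 in the analysis panel. R² is the squared Pearson
correlation of unphased dosage vectors (the composite-LD estimator). Ties on
best R² break by smaller base-pair distance, then lexicographic id.
Monomorphic variants have undefined LD and count as unmatched. The ±500 kb
window is standard proxy-lookup practice; the direct-match count is
symmetric in A and B, proxy counts need not be.

### Agreement statistics

* `pearson_r` on the continuous scores.
* The 7×7 cross-classification carries counts plus three percentage
  matrices; `row_pct` rows sum to 100, `col_pct` columns sum to 100,
  `cell_pct` sums to 100. Rendered cells print `(row%, col%, cell%)` to one
  decimal with half-up rounding — the order and format the published
  reclassification tables actually use.
* `topk_concordance(a, b, k)`: share of a's top k% (percentile ≥ 100 − k)
  with b-percentile ≥ 100 − k.
* Odds ratios: logistic fit of the outcome on an indicator for the top-k%
  group versus the middle-quintile reference (percentile in [40, 60)),
  adjusted for age, sex, genotyping array and PC1–5; sex (or a single-level
  array) is dropped automatically when constant, matching the female-only
  breast-cancer setting. Wald 95% CIs. An empty case or control cell in the
  reference group raises an explicit error rather than returning a divergent
  estimate.
* AUC is the rank-based Mann–Whitney estimator (ties one half) on fitted
  probabilities from two model variants: crude (score + array + PCs) and
  multivariable (adding age and sex).
* Continuous NRI follows the up/down decomposition
  `[P(up|case) − P(down|case)] + [P(down|ctrl) − P(up|ctrl)]` with exact
  ties contributing zero (Pencina's convention); the model containing
  score B is the "updated" model. Categorical NRI applies the same
  decomposition to movements across the seven percentile bins.
* Bootstrap CIs are percentile intervals (2.5/97.5) over 1000 seeded
  resamples of individuals; the statistic is recomputed from the fitted
  per-individual risks rather than refitting the model per replicate — the
  cheap standard variant, adequate at these sample sizes. BCa was judged
  unnecessary for this surface. Wald CIs (not bootstrap) are used for ORs.

Logistic fits delegate to maximum likelihood via Newton/IRLS (statsmodels),
100 iterations, tolerance 1e−8; non-convergence, separation or non-finite
standard errors raise an error, never a silent estimate.

### The Gaussian-copula oracle

For standardized scores jointly normal with correlation ρ, the expected
top-k% concordance is `P(Y > z | X > z)` with `z = Φ⁻¹(1 − k/100)`,
computed as `(100/k)·∫_z^∞ φ(x)·Φ̄((z − ρx)/√(1 − ρ²)) dx` by adaptive
quadrature on [z, z + 10] (absolute tolerance 1e−6; the mass beyond z + 10
is below machine precision for relevant k). A Monte-Carlo mode cross-checks
the quadrature; the tests also verify it against the bivariate-normal
orthant probability computed independently. The oracle is strictly
increasing in ρ, bounded in [k/100, 1], and symmetric in the two scores.

It doubles as the explanation layer for the headline numbers: at r = 0.65
the copula predicts 22.4% top-1% and 34.9% top-5% concordance, and at
r = 0.66 it predicts 23.2% and 35.7% — all within a percentage point of the
empirically published 23.1/35.7 (breast cancer) and 22.9/35.8
(hypertension). The published dementia concordance (22.7% at r = 0.51)
exceeds the bivariate-normal prediction (~13%) substantially, consistent
with the markedly non-normal joint distribution of scores built from only
57 and 39 SNPs; no quantitative claim is pinned to it.

## The synthetic-data generator

What it emulates, and how:

* **LD-block dosages.** Each individual gets two haplotypes per block; a
  haplotype is a latent AR(1) Gaussian across the block's variants
  (marginal N(0,1), lag-1 correlation `within_block_corr`), thresholded at
  `Φ⁻¹(MAF)` to an allele indicator. Genotype = sum of haplotypes, so
  Hardy–Weinberg holds by construction and the mean dosage is 2·MAF.
  Blocks are independent, laid out 10 Mb apart (beyond any proxy window)
  with 5 kb spacing inside a block. Dichotomization attenuates correlation:
  latent 0.95 yields adjacent dosage R² ≈ 0.57–0.64, and R² > 0.8 requires
  latent ≈ 0.995 *and* similar MAFs at the two variants — a real
  constraint, not an artifact: the correlation of two binary variables with
  dissimilar frequencies is bounded well below 1. Optional uniform jitter
  produces imputed-style non-integer dosages (off by default). Info scores
  are simulated metadata on a configurable range; the pipeline only
  thresholds them.
* **Paired weight sets.** Score B shares `round(shared_fraction·n_snps_a)`
  of A's variants; shared weights are bivariate normal with correlation
  `weight_corr`, so `shared_fraction = 1, weight_corr = 1` degenerates to
  identical files. Under variant independence the induced inter-score
  correlation is computable in closed form from the weights and
  Hardy–Weinberg variances (`analytic_score_correlation`), which the tests
  use for parameter recovery. The defaults (313 variants, 72% shared,
  weight correlation 0.9) emulate the published breast-cancer pair: 225 of
  313 variants shared and an induced r near 0.65.
* **Outcomes.** Logistic model on the standardized true score A plus
  standardized age and a sex indicator, intercept solved by Brent root
  finding so the realized marginal prevalence hits `prevalence_target`
  (default 5%, the rarer-outcome regime); or a thresholded Gaussian
  quantitative trait for the hypertension-style "measured value above a
  cutoff" ascertainment. Covariates: age Uniform(40, 70), sex balanced or
  female-only, two genotyping arrays at 90/10, five standard-normal PCs.
  Sample-QC flags are independent Bernoulli per flag at configurable rates
  (defaults ~3% related, 0.2% sex-discordant, 0.2% het/missingness — small,
  UK-biobank-like orders of magnitude).
* **Planted pathologies** for QC tests: strand-ambiguous variants whose
  dosage columns are laid down with an *exact* allele count just under 0.5
  (so the realized MAF deterministically exceeds the 0.49 rule), rare
  variants at an exact MAF near 0.003, low-info variants, allele-swapped
  score entries (alleles exchanged, weight negated — the same score
  published against the other allele) and strand-flipped entries.

Randomness: one master seed; panel, score and cohort generation use
deterministically spawned child streams, so identical configurations are
bit-identically reproducible.

What the generator does **not** emulate: realistic human LD maps and allele
frequency spectra, ancestry admixture and PC structure correlated with
genotype, genotyping error, X-chromosome dosages, or any mechanism by which
two real scores disagree beyond partial SNP sharing and noisy weights
(different derivation GWAS, winner's curse, sample overlap). Passing tests
therefore demonstrate the correctness of the *measurement machinery* under
controlled joint distributions, not that any real score pair behaves like
the synthetic one.

## Problem sizes and numerical choices

Test simulations run at n = 2,000–50,000 individuals and 30–640 variants —
sizes chosen so the full suite completes in well under a minute per module
while keeping Monte-Carlo error far below the asserted tolerances; the
copula reproduction uses two million pairs, matching the scale at which the
published percentages are distinguishable from their Gaussian predictions.
Replicate-based checks (null OR coverage, strong-effect OR recovery) use 100
replicates of n = 6,000 with prevalence 0.25–0.30, large enough that the
top-1% bin essentially never lacks cases (which would leave the Wald CI
undefined). For the strong-effect check the covariate effects are set to
zero so the Monte-Carlo marginal OR equals the covariate-adjusted estimand
(logistic odds ratios are non-collapsible in general).

Degenerate inputs are errors, not warnings: empty score after QC, constant
score at standardization, missing outcome class, monomorphic variants in LD,
empty reference stratum in OR estimation. Percentages are rounded half-up to
one decimal only at the rendering/comparison layer; all internal matrices
are exact.

## Known limitations

* The LD-proxy search measures R² in the analysis panel itself; with a real
  external reference panel the overlap counts would differ.
* NRI from bootstrapped fitted risks ignores model-refit variability;
  at biobank scale this is negligible, at n ≲ 1,000 it is not.
* The bivariate-normal oracle is exactly that — scores built from few SNPs
  (tens) have visibly non-normal joint tails and will beat or miss the
  copula prediction, as the dementia pair illustrates.
* Strand flips of palindromic variants are unresolvable from alleles alone
  and are treated as mismatches; no frequency-based rescue is attempted.
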