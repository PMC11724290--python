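# Methods

## Model overview

`ttwas` implements a transcriptome-wide association (TWAS) framework in
which a gene's expression prediction model draws on two classes of genetic
predictors:

* **cis-variants** — variants within ~1 Mb of the gene, restricted to
  TF-occupied cis-regulatory elements prioritized by a genome-wide screen
  (below);
* **TF-linked trans-variants** — cis-regulatory variants of transcription
  factors whose ChIP-seq binding sites fall within ±20 kb of the gene's
  TSS.  A cis-variant of a TF can perturb the TF's own expression and
  thereby the expression of its distal targets, so it acts as a
  trans-predictor for those targets (>1 Mb away or on another chromosome).

Training is two-stage.  Stage one fits a group lasso over the gene's
TF-labelled trans-variant groups,

    min_beta  ||y - X beta||_2^2 + lambda * sum_{g=1}^{G} w_g ||beta_g||_2,

whose l2-per-group penalty zeroes out whole groups (between-group
sparsity) while keeping selected groups dense (within-group retention) —
matching the biological reading that either a TF regulates the gene (all
of its cis-variants are candidate predictors) or it does not.  Variants in
groups surviving regularization, provided the grouped model itself
predicts expression in cross-validation, are pooled with the prioritized
cis-variants and refit with a standard elastic net (stage two).  Models
are retained for association only when their 10-fold cross-validated R^2
(squared Pearson correlation of pooled out-of-fold predictions) exceeds
0.01.

Association with a trait uses GWAS summary statistics only:

    Z_g = sum_{l in Model_g} w_lg (sigma_l / sigma_g) beta_l / se(beta_l),

with per-variant dosage SDs `sigma_l` and predicted-expression SD
`sigma_g = sqrt(w' Gamma w)` estimated from a reference genotype panel.
Gene-level significance is Bonferroni-corrected over the genes with
retained models.  For each significant gene the *lead variant* is the
nonzero-weight model variant with the largest GWAS |z|; when it is a
trans-variant, its source TF defines a TF→gene edge in the regulatory
network output.

## Prioritization steps

**TF cis-variant sets (Step I).**  A candidate cis-variant of a TF is kept
iff (a) it falls in open/regulatory chromatin (DHS ∪ enhancer ∪ promoter)
and (b) it is linked to the TF by at least one of: nominal eQTL
significance (P < 0.05) in any supplied eQTL table; location in the TF's
promoter (TSS ± 2 kb); location in an enhancer linked to the TF; or
location in one anchor of a chromatin interaction whose other anchor
overlaps the TF promoter.  The eQTL filter accepts significance in
*either* supplied table (target tissue or whole blood); this is
configurable via which tables are passed.

**TF–gene pairing (Step II).**  A TF is paired with every gene for which
any ChIP-seq peak interval overlaps the closed window [TSS − 20 kb,
TSS + 20 kb]; the TSS is strand-aware (transcript end for minus-strand
genes).  Interval overlap (not peak midpoint) is used, the standard
ChIP-seq convention.

**Cis-variant screen.**  Per-variant GWAS chi-squared statistics (z² of
beta/se) are regressed on each TF's binary binding status with ordinary
linear regression; TFs associated at two-sided P < 0.05 contribute their
occupied variants, ordered by TF significance then variant |z|, truncated
to a target count (50,000 at production scale).  A mixed-model variant of
this screen would require a random-effect structure that is not defined
here; plain linear regression is the determinate choice.

**Trans-group assembly.**  One group per paired TF, containing the TF's
cis-variant set minus any variant within 1 Mb of the target gene body on
the same chromosome; empty groups are dropped and groups are ordered by
TF name for determinism.

## Numerical choices

* **Group-lasso solver.**  FISTA with a group soft-threshold prox; the
  Gram matrix is precomputed when n ≥ p.  Convergence is certified by the
  Fenchel duality gap (default relative gap 1e-8 for final fits, 1e-4
  inside cross-validation, where only the ranking of lambdas matters).
  λ_max is computed in closed form; the path uses 100 log-spaced values
  down to 1e-3·λ_max with warm starts.  Group norms are weighted by
  sqrt(group size) (Yuan–Lin weighting, config flag) so large groups do
  not dominate selection.
* **Lambda choice.**  Out-of-fold MSE over a K-fold split (default 5),
  with the **one-SE rule**: the sparsest lambda whose CV error is within
  one standard error of the minimum.  The plain CV-minimum systematically
  admitted noise groups (group-level false inclusion far above the
  targeted ~20%); the one-SE rule is the standard remedy and is the
  package's default.
* **Elastic net.**  Fixed mixing α = 0.5 (the common TWAS/PredictDB
  convention), penalty chosen by internal CV; genotypes are standardized
  for fitting and weights are mapped back to the per-allele scale.
  Seeds control fold assignment only.
* **Covariates** (genotyping PCs, age, PEER factors) are nuisance terms:
  expression is residualized on [1, C] by least squares before penalized
  fitting.  Collinear covariate columns are dropped via the
  pseudoinverse with a warning.  PEER factors are consumed, not
  estimated.
* **One grouped fit per gene.**  All G groups enter a single group lasso
  (the joint objective above) rather than G separate per-TF models; the
  per-TF reading is recoverable by passing singleton group lists.
* **Degenerate inputs.**  Monomorphic variants are excluded from GWAS
  summaries (flagged beta 0, se ∞) and from elastic-net design matrices;
  all-zero-weight genes are omitted from the weight database with a
  warning; σ_g = 0 genes are skipped in association; a small ridge
  (1e-8) on the panel covariance guards positive definiteness.
* **Harmonization** matches variants on (chrom, pos, unordered allele
  pair); a swapped effect allele flips the GWAS beta sign; mismatched
  allele pairs at the same position are treated as missing.
  Strand-ambiguous variants are retained (synthetic data has known
  strand); real-data use can drop them upstream.

## Synthetic cohorts

The generator emulates the structure a TWAS simulation study needs, not
real human genomes:

* **Genotypes** are two Hardy–Weinberg haplotypes per sample, each a
  thresholded latent Gaussian AR(1) process within an LD block
  (correlation `ld_rho` between adjacent latents, default 0.3).  Allele
  frequencies equal the layout MAF in expectation for every seed, so two
  cohorts drawn from one layout share frequencies and LD structure while
  individuals differ — the reference-panel/GWAS-cohort relationship the
  association statistic assumes.  Thresholding attenuates the realized
  haplotype correlation relative to the latent `ld_rho`; only the
  monotone relationship is relied on.
* **Expression** is additive over a causal layout: by default 200 cis
  candidate variants per gene with 5 (or 10) causal among them, and 10
  trans regions of 50 variants each with 3 (or 4) causal regions
  contributing 5 (or 10) causal variants apiece; causal variants require
  MAF > 1%.  Effects are N(0, 1) before rescaling; the realized cis and
  trans genetic components are empirically rescaled to the target
  heritability fractions and Gaussian noise supplies the remainder.
* **Phenotypes**: under *causality* the trait's genetic component is the
  simulated expression (mediation); under *horizontal pleiotropy* the
  same causal variants act with independent N(0, 1) effects.  Either
  component is rescaled so that σ_g²/(σ_g² + σ_e²) equals the trait
  heritability; binary traits threshold the liability at the median
  (prevalence 0.5).  Both scenarios therefore share the same marginal
  phenotype variance at equal trait heritability.
* **Annotations** are wired to a recoverable ground truth: every planted
  TF cis-variant lies in a DHS and is a significant eQTL of its TF (a
  subset carries additional promoter/enhancer/interaction evidence), and
  every planted TF–gene pair has a peak within ±20 kb of the gene TSS, so
  the prioritization steps recover the planted structure exactly and
  end-to-end recovery is testable.

What the generator does *not* emulate: coalescent-realistic LD decay,
population structure and admixture, imputation noise, non-additive
effects, and expression confounding beyond explicit covariates.  Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated generative model, not performance on real cohorts.

## Simulation benchmarks and problem sizes

The type-I error experiment draws balanced binary phenotypes independent
of genotype, builds logistic-regression GWAS summary statistics, and runs
the entire pipeline per replicate; the headline number is the family-wise
rejection fraction at the Bonferroni-corrected 0.05 level.  Expression in
the null world carries genuine heritability (cis 0.15, trans 0.2) so that
models pass the retention rule and genes are actually tested.  Because
the group-lasso trans-selection stage depends only on the fixed reference
cohort, it is computed once and memoized across replicates; the
prioritization, elastic net and association stages re-run per replicate.

The power experiment simulates one causal gene per replicate and compares
four methods: the TF-grouped trans method; a random-group control with
identical group count and sizes but non-causal variants; an all-cis
elastic net (±1 Mb); and an elastic net on 200 random cis candidates.
Success is a Bonferroni-corrected P below 0.05.  The GWAS cohort for
power cells is sized like a 1000 Genomes European panel (n = 503), the
regime in which method orderings are visible rather than saturated;
cohort sizes, variant counts and replicate numbers are configurable.

Desk-scale defaults keep the full suite tractable on one CPU: the null
experiment uses 200 genes × 24 cis candidates plus 10 TFs × 20
cis-variants (5,000 variants), reference n = 500, GWAS n = 2000, 20
replicates; power cells use 5 trans regions × 10 variants, 100 cis
variants (50 candidates), n_ref = 400, 25 replicates per cell.
Production-scale settings (50 K prioritized variants, 1000 replicates,
10 × 50 trans groups) are plain configuration changes.

## Downstream statistics

Gene-set enrichment uses the upper-tail hypergeometric probability
P(X ≥ x) over a protein-coding background (N = 19,291 at production
scale); TF enrichment in the TF→gene network uses a two-sided Fisher
exact test (point-probability summation); CRISPR essentiality flags genes
whose median CERES dependency score across cell lines is strictly below
−0.5.  All three are validated against exact rational-arithmetic
enumeration oracles in the test suite.

## Known limitations

* The simulated LD is block-wise AR(1); there is no inter-block LD, so
  the cis-variant screen faces easier conditions than real GWAS data.
* The GWAS effect-allele convention assumes biallelic, strand-resolved
  variants; palindromic-variant ambiguity is a real-data concern the
  synthetic cohorts do not exercise.
* The per-TF "significant model" criterion is operationalized as CV R^2
  of the grouped fit ≥ 0.01 (aligned with the downstream retention
  floor); other definitions are possible and config-exposed.
* Logistic GWAS uses damped Newton iterations without separation
  handling beyond step damping; quasi-separated variants at desk sample
  sizes get large but finite estimates.
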