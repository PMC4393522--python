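# Methods

## Problem and model

GWAS report per-SNP association Z-scores; most regulatory (eQTL) and
protein-function variants that plausibly mediate a gene's effect on a trait
are either unmeasured on genotyping arrays or individually too weak to reach
significance.  This package tests, per gene, the *joint* effect of all
functional SNPs annotated to that gene, using only summary statistics and an
external reference genotype panel:

1. **Harmonization.**  Every Z-score is oriented to the reference panel's
   ALT allele (sign flips where the effect allele is the panel REF; strand
   complements resolved where unambiguous; A/T and C/G SNPs dropped by
   default because their strand cannot be inferred from alleles alone).

2. **Summary-statistic imputation.**  Under the null, the vector of Z-scores
   is asymptotically multivariate normal with covariance equal to the local
   LD (genotype correlation) matrix Σ.  For unmeasured annotated SNPs the
   conditional expectation given the measured Z-scores is

       Ẑ_u = Σ_um (Σ_mm + λI)⁻¹ Z_m,
       I_u = Σ_um (Σ_mm + λI)⁻¹ Σ_umᵀ,

   computed per non-overlapping 0.1 Mb prediction window (anchored at
   coordinate 0, half-open), conditioning on all measured SNPs in the window
   extended by 0.2 Mb flanks on each side.  Ẑ_u is normalized per SNP by
   √diag(I_u) (element-wise, not a matrix square root: imputed SNPs are used
   individually downstream), and SNPs with information below 0.3 are
   discarded.  The solve uses a Cholesky factorization of the
   ridge-adjusted Σ_mm; no explicit inverse is formed.

3. **Gene-level test.**  For a gene with m usable SNPs in k functional
   categories (PFS, TFBS, miRNA structure, miRNA target, cis-eQTL,
   trans-eQTL), with Z the SNP Z-vector, Y = diag(√info), and S the k×m
   signed weight matrix, the category scores are U = WZ with W = SY, and
   Σ_U = W Σ_G Wᵀ where Σ_G is the ridge-adjusted LD matrix of the gene's
   SNPs.  The omnibus statistic T = Uᵀ Σ_U⁻¹ U is χ²_k under the null.
   Σ_U⁻¹ is a rank-truncated eigen pseudo-solve (eigenvalues below 1e-8 of
   the largest dropped), with the degrees of freedom equal to the numerical
   rank, so duplicated or collinear categories reduce df instead of
   destabilizing the statistic.  Per-category two-tailed p-values on the
   standardized U_j are reported post hoc.

4. **Background-enrichment adjustment.**  Signal-rich studies inflate T
   genome-wide even at null genes.  With N tested genes, the per-df
   noncentrality λ = max(mean_i (T_i − k_i)/k_i, 0) is estimated and each
   gene's p-value re-assessed under a noncentral χ²(k_i, ncp = λ·k_i).
   Two readings of the printed formula exist; we take "noncentrality per
   df" literally: the mean standardized excess per df, with total ncp
   scaling with df.  At λ = 0 the adjustment is exactly central.  It is
   applied over all successfully tested genes (degenerate genes skipped
   before the mean), optional via a flag, default on.

5. **Multiplicity.**  Benjamini–Hochberg q-values over the (adjusted)
   gene p-values; q < 0.05 significant, 0.05 ≤ q < 0.16 suggestive.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| prediction window | 100 000 | bp | imputation locality |
| flank (per side) | 200 000 | bp | conditioning context; "two flanking regions" read as one per side |
| info threshold | 0.3 | — | discard poorly imputed SNPs |
| ridge λ | 2/n | — | n = reference-panel **samples** (not haplotypes); stabilizes near-singular LD |
| FDR α | 0.05 | — | significance |
| suggestive α | 0.16 | — | AIC-equivalent p threshold |

Cross-chromosome LD is fixed at exactly 0 (trans-eQTL SNP sets legitimately
span chromosomes; empirical cross-chromosome correlation at reference-panel
sample sizes is pure noise).  LD is the Pearson correlation of ALT-dosage
columns (genotype, not haplotype, correlation).  Coordinates are 1-based
inclusive throughout.

Annotation weights are bound to the annotation's stated reference allele
(negative = reference allele predicted to decrease expression) and re-signed
at assembly to the harmonized panel-ALT orientation, which makes U, Σ_U and
T invariant to allele-orientation bookkeeping (tested).  Duplicate
(SNP, gene, category) rows are rejected rather than merged; gene start/end
in the output are the span of the gene's used SNPs on its modal chromosome,
since the annotation schema carries no gene coordinates.

## Synthetic data

The generator emulates the structure the method assumes, at desk scale:

* **Panels.**  Haplotypes are a latent Gaussian AR(1) process (adjacent-SNP
  latent correlation `ld_decay`, default 0.95) thresholded at Φ⁻¹(MAF);
  dosage = sum of two haplotypes.  This yields exponentially decaying,
  controllable LD.  The realized dosage correlation is attenuated below the
  latent value by the liability threshold (phi-coefficient of a thresholded
  bivariate normal; checked against that closed form in the tests): latent
  0.95 gives mean adjacent dosage r ≈ 0.7 at 2 kb spacing.  The default was
  chosen so that array-style masked SNPs re-impute at information ≈ 0.8,
  matching the imputation-quality regime of dense same-population reference
  panels.  Locus-level properties (positions, alleles, MAFs) are governed by
  `locus_seed`, shared between a GWAS cohort source and a differently seeded
  analysis panel: two samples from the same population, the mismatch a
  summary-statistics method faces in practice.
* **GWAS.**  Cohorts of n = 2000 are drawn with replacement from a simulated
  super-panel (n = 1000); phenotypes are standard normal (continuous) or a
  random half assigned case status (binary); per-SNP Wald Z-scores come from
  simple linear regression (closed form) or a two-parameter Newton–Raphson
  logistic fit vectorized across SNPs (verified against statsmodels Logit).
* **Annotations.**  Toy databases assign contiguous SNP blocks to genes
  with signed weights ± Uniform(0.2, 1); the "structured" variant places
  non-overlapping 5-SNP gene blocks separated by 15 unannotated backbone
  SNPs that serve as imputation conditioning and decorrelate neighboring
  genes.

What the generator does **not** reproduce: haplotype-block LD (AR(1) decay
is smoother and has higher effective rank than real block structure, which
makes window-level imputation slightly *harder* than real data),
population stratification, allele-frequency drift between cohort and
reference, imputation-array ascertainment, and genuine effect-size
architectures.  Passing tests therefore demonstrate internal statistical
correctness and calibration under the stated model, not performance on any
particular real cohort.

## Experiments

* **Type-I error** (50 replicates × 100 genes, both phenotypes): each
  replicate simulates a null GWAS, hides 30% of annotated SNPs (re-imputed
  by the pipeline), and analyses against an independently drawn n = 500
  reference panel.  Rates are fractions of gene-level raw p ≤ nominal; the
  Monte-Carlo SE is taken across replicate-level rates, which is robust to
  the residual LD between neighboring genes.  The experiment also runs the
  no-masking arm; comparing the two isolates the contribution of
  imputation noise.  Desk-scale sizes (n_panel = 500, n_gwas = 2000,
  100 genes × 5 SNPs, 50 replicates) were fixed once as the package's
  simulation conditions.
* **Power** (200 replicates): one gene with three equally weighted causal
  eQTLs spaced 10 SNPs apart (weak pairwise LD), effect size β = 0.10 per
  ALT allele, putting each marginal Z near 3 — two orders of magnitude short
  of genome-wide significance — while the pooled 1-df category score
  concentrates the signal.  The reported quantity is the fraction of
  replicates in which the joint gene p beats the gene's best univariate
  SNP p.
* **Calibration**: mean T/df under null MVN draws with panel LD treated as
  truth; variance of normalized imputed Z at info > 0.8 under the same
  regime.

## Numerical choices and degenerate inputs

* Monomorphic panel SNPs are excluded at load (LD undefined).
* A window with no measured SNPs leaves its targets at info 0 (not
  missing), so the threshold filter is total.
* Imputed info is clipped to [0, 1]; a target duplicating a measured SNP
  reproduces the measured Z exactly at λ = 0 (tested).
* Genes whose Σ_U is numerically zero-rank are skipped with a recorded
  reason; λ (enrichment) is estimated over the remaining genes.
* p-values are floored at 1e-300 before BH to keep the step-up finite.
* Ties in window assignment resolve by half-open [start, end) intervals.

## Known limitations

* With a small reference panel (n = 500) and ~250 conditioning SNPs per
  extended window, imputed Z-scores overfit reference noise; their variance
  exceeds 1 by several percent under panel mismatch, which is visible as a
  mild (≈1.1×) relative excess of gene-level type-I error at stringent
  thresholds.  The ridge and info threshold damp but do not remove this;
  larger panels do (verified: variance 1.05 at n = 2000).
* The enrichment λ is a genome-wide scalar; locally clustered enrichment is
  not modeled.
* Only autosomal, biallelic SNPs are handled; X chromosome and indel-aware
  harmonization are out of scope.
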