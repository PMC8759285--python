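# Methods

This note documents the models, estimators and numerical choices in
`ptrs-kit`, what the synthetic cohorts do and do not emulate, and the
decisions taken where the design was genuinely open.

## Predicted transcriptome

Predicted expression is the linear imputation T̂_ig = Σ_j X_ij w_gj over a
gene's cis variants; missing dosages are mean-imputed per variant at use
time (the genotype container itself retains missingness). Weight models are
matched to a genotype panel by `variant_id` with an allele check: equal
effect/other alleles pass through, swapped alleles negate the weight, and
anything else is dropped with a log message. Palindromic (A/T, C/G) model
variants are dropped outright because a strand flip is indistinguishable
from an allele swap for them; we prefer losing a variant to guessing its
orientation. No strand-complement rescue is attempted for non-palindromic
mismatches either — identifiers that disagree on alleles are treated as
different variants.

Two normalizations are used downstream, for different purposes:

* **standardization** (mean 0, sd 1, denominator N−1) within the population
  being scored or trained on — used by both PTRS constructions and by the
  scoring of target cohorts;
* **inverse normalization** T̃ = Φ⁻¹(rank/(N+1)), ranks increasing, average
  ranks on ties — used for variance-component estimation, where the random
  effect is assumed N(0,1) per feature. Ties are real on toy dosage data
  (few cis variants ⇒ few distinct predicted values), hence average ranks;
  on continuous data they are measure-zero.

For multi-tissue analyses each gene's N×K cross-tissue matrix is
column-centered and decomposed by SVD; unit-norm left singular vectors with
singular value ≥ 1/30 of the gene's maximum become features `gene#k`.
Centering makes the eigenfeatures location-free; we emit unit-norm vectors
rather than scaling by singular values because the downstream
inverse-normalization renders per-feature scale irrelevant. Genes absent
from some tissues use whichever tissues carry them, maximizing coverage.

## Variance components (PVE, chip heritability)

The mixed model y = Cα + g + ε, g ~ N(0, σ_g²K), ε ~ N(0, σ_e²I) with
K = FFᵗ/M is fitted by restricted maximum likelihood. We parameterize
h = σ_g²/(σ_g² + σ_e²) so that PVE = h, profile out the total variance and
the fixed effects in closed form given h, and maximize the profiled REML
criterion with a 64-point grid followed by bounded scalar refinement
(tolerance 1e−6). When K is built by `relatedness_from_features` the feature
factor is kept, and the eigenstructure comes from an economy SVD of F/√M —
O(N·M) per criterion evaluation instead of O(N²) — with the orthogonal
complement of the feature span handled analytically (eigenvalue 0). Boundary
optima (h ≈ 0 or 1) are flagged. The standard error of PVE is the inverse
observed information in the h parameterization, i.e. 1/√(−∂²ℓ_R/∂h²) by
central differences at the optimum; it is a per-fit quantity, distinct from
any across-trait dispersion a multi-trait study would report.

REML (rather than ML) avoids the downward bias from estimating α; the
single-K eigendecomposition makes the fit exact rather than iterative. The
test suite pins the estimator against a brute-force maximization of the
explicit restricted likelihood over a dense (σ_g², σ_e²) grid.

Chip heritability uses the same estimator with column-standardized genotype
dosages as F. All simulated variants are used; real-data pruning to
"independent" SNP sets is a data-curation concern outside this package's
scope.

## GWAS, filters, clumping, PRS

The association scan regresses the trait (original scale) on
[1, covariates, dosage] per variant. It is vectorized through the
partialling-out identity — y and all dosage columns are residualized on the
covariate design once, and the dosage term's estimate, with full-model
degrees of freedom, equals the full OLS fit (verified against a per-variant
OLS oracle at 1e−10). The same engine produces the PrediXcan-style gene
associations, applied to predicted-expression columns, so the two scans are
identical code by construction.

Variant filters: minor allele frequency ≥ 0.001 and Hardy–Weinberg
equilibrium p ≥ 1e−10. HWE is a 1-df χ² goodness-of-fit test on hard calls
obtained by rounding dosages — an adaptation needed because dosages, not
called genotypes, are the native representation here; monomorphic variants
are trivially in equilibrium but fail the MAF filter anyway.

LD clumping traverses variants by increasing p (ties broken by chromosome,
then position, for reproducibility) and keeps a variant unless its squared
dosage correlation with an already-kept variant within ±250,000 bp on the
same chromosome exceeds 0.1, computed on mean-imputed discovery dosages.
Gene-based clumping is the same greedy rule in predicted-expression space
with no distance window and a strict < 0.1 comparison. The PRS path uses
thresholds {5e−8, 1e−7, 1e−6, 1e−5, 1e−4, 1e−3, 0.01, 0.05, 0.1, 0.5, 1};
the gene path uses {1e−6, 5e−6, 1e−5, 5e−5, 1e−4, 5e−4, 1e−3, 5e−3, 0.01,
0.05, 0.1, 0.5, 1}. Threshold comparisons are ≤ throughout, for both
variant and gene paths.

## Elastic-net PTRS

The objective (1/N)‖Y − Xβ − β₀‖² + λα‖β‖₁ + λ(1−α)‖β‖₂² is minimized over
the joint vector of transcriptome and covariate coefficients with the
intercept unpenalized. By default the covariate block is penalized exactly
as the transcriptome block — that is how the objective is written — and a
`penalize_covariates=False` switch exempts it, since common practice
differs. λ_max = max_j |(2/N)X_jᵗ(Y − Ȳ)|/α is the smallest λ at which the
all-zero coefficient vector (with β₀ = Ȳ) satisfies the KKT condition; it is
estimated on the first 1000 rows by default (a cost-saving subsample; on
simulated cohorts row order is arbitrary). The grid is 20 log-equispaced
points from 1.5·λ_max down to λ_max/10⁴, fitted in descending order with
warm starts.

The solver is FISTA — proximal gradient with Nesterov acceleration and a
monotone restart — using the soft-threshold prox, step 1/L with L bounded by
10 power iterations on XᵗX plus the ridge curvature (1% safety margin), and
exact profiling of the intercept each iteration. A λ is accepted as
converged only when the relative objective change falls below 1e−10 *and*
the KKT residual is ≤ 1e−6; the relative-change test alone can trigger while
the solution is still loose at small λ, so the certificate is part of the
stopping rule. An optional mini-batch mode (per-epoch shuffling under the
seed) pre-conditions the full-batch solve for large N; the final polish is
always full-batch, keeping results batch-size-independent to solver
tolerance.

"Non-degenerate" models are those with at least one nonzero transcriptome
coefficient; walking λ from the top, the first 11 such models form the PTRS
path, matching the number of PRS thresholds so both families offer the same
number of candidates. α is fixed at 0.1 (nearby values behave similarly and
α selection is out of scope).

## Accuracy, portability, combination

Partial R̃² is computed through the null-model projection,
𝒞(u,v) = uᵗv − uᵗHv with H from a QR factorization of [1, C]; this equals
1 − SSE_full/SSE_null exactly (property-tested at 1e−10) and is invariant to
affine transforms of the score. A score lying in the covariate span gets
R̃² = 0 with a degeneracy flag.

Hyperparameters are selected by 10 repeated 50/50 validation/test splits
(seeds seed+0..9, recorded in the report; odd cohorts give the validation
half the extra sample); the validation-R̃²-maximizing hyperparameter is
scored on the test half and the mean test R̃² is reported. Ties break toward
the smaller model support.

Portability divides a score's accuracy in a target set by its accuracy in
the reference target set; the reference against itself is exactly 1.
The combined score c₁·PRS + c₂·PTRS is calibrated per (t, λ) pair by least
squares of the covariate-residualized trait on the two scores (residualizing
matches the partial-R̃² metric being optimized and subsumes the intercept),
using half of the validation set; the other half selects the best pair, and
the untouched test half reports its accuracy. Numerically collinear pairs
(|r| > 0.9999) fall back to a small ridge jitter, flagged. Score-family
comparisons across traits use the two-sided paired Wilcoxon signed-rank test
with the exact null for ≤ 25 nonzero differences.

## Ancestry QC

Each population's individuals are modelled as multivariate normal in
top-10-PC space (configurable dimension); the similarity of individual i to
population k is the log density S_ik, and individuals with S_ik ≤ −50 in
their assigned population are removed in a single pass (models are fitted on
the pre-filter samples and applied once). The cutoff is exposed as a
parameter; −50 corresponds to a Mahalanobis distance of ≈ 9 sd in 10
standard-normal dimensions, so false removals of correctly labelled samples
are rare (< 1% property-tested). A ridge of 1e−8·trace/d guards
near-singular covariance fits.

## Synthetic cohorts

The generator emulates the ingredients the estimators above need, not human
demography. Ancestral allele frequencies are Uniform(0.05, 0.95); each
population's frequencies are Beta draws with variance F·p(1−p)
(Balding–Nichols), F being the divergence knob. Dosages are Binomial(2, p)
per variant, optionally with local LD from an AR(1) Gaussian copula over
adjacent variants on each of the two haplotypes (marginal frequencies are
preserved by thresholding at Φ⁻¹(p)). Each gene receives a block of
consecutive cis variants with N(0,1) weights; a second "tissue" or
"population" store can re-draw a fraction of genes' weights.

Traits follow Y = Σ C_l a_l + Σ_g T̃_g β_g + Σ_j X_j b_j + ε with shared
gene effects β_g across populations and direct variant effects whose
cross-population correlation is configurable (0 = fully
population-specific). The mediated, direct and noise components are
orthogonalized in sample (cis and causal variants overlap, so raw components
correlate) and rescaled so the realized variance fractions equal the
configured `mediated_h2`/`direct_h2` exactly — parameter-recovery tests then
compare against the nominal values directly. Covariates are age, sex, age²,
sex×age, sex×age² with N(0, 0.3²) effects on standardized columns, plus top
pooled-genotype PCs (default 5) carrying no generative effect. Predicted
expression is treated as the ground truth the weight model defines; no
expression measurement noise is added, because PTRS operates on predicted,
never measured, expression.

Defaults (1000 individuals per population, 500 variants, 100 genes with 3
cis variants each, divergence 0.1, mediated h² 0.3, direct h² 0.2) are
desk-scale study conditions chosen so that every estimator is comfortably
identified; the heavier parameter-recovery tests use 2000 individuals and
300 genes, where the REML sampling error of a single fit (≈ 0.03–0.07)
averages below the ±0.05 recovery band over 20 replicates. What the
simulator does **not** emulate: realistic LD beyond first-order decay,
recombination maps, rare-variant architecture, sex chromosomes, binary
traits, assortative mating, or genotyping error. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions, not
real-data performance.

## Numerical details and edge cases

* Dosage bounds [0, 2] are enforced on load; positions are 1-based (VCF
  convention); variant matching is by `variant_id` plus allele check, and
  how a study maps model variant IDs onto its genotype IDs is the caller's
  responsibility.
* The native dosage-table dialect writes floats via shortest-repr and reads
  them with round-trip precision, so write→read is bit-exact.
* Zero-variance features are dropped (standardization, GWAS, clumping) with
  log messages rather than propagating NaNs.
* REML rejects covariate designs that are rank-deficient (naming the
  collinear columns) and relatedness matrices that are asymmetric or
  indefinite beyond tolerance.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit configuration; repeated runs are bit-identical, and the
  experiment driver embeds the package version, seed and a config hash in
  its report.

## Known limitations

Single relatedness component only (no GxE or multiple kinships); continuous
traits only; the elastic net is dense in memory (N×M design), adequate for
cohorts up to ~10⁵×10⁴ but not biobank-by-genome scale; portability ratios
are reported without confidence intervals (the per-repeat spread in the
evaluation report is the provided uncertainty signal).
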