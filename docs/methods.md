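# Methods

This note documents the models, the synthetic cohort generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Synthetic cohort

The generator produces a desk-scale rendition of a population-scale
single-nucleus brain cohort. Defaults: 200 donors, 5 cell types, ~15
nuclei per donor per cell type (NB-distributed with size 10, as the
per-donor nucleus count distribution is not pinned down by any reference
we rely on — it is configurable), NB dispersion θ = 10, donor
random-intercept SD 0.3 on the log scale, MAF uniform on (0.05, 0.5].

* **Genotypes.** Per variant, dosages follow Hardy–Weinberg proportions.
  Ancestry structure is a 50/50 mix of two subpopulations whose
  frequencies are Balding–Nichols draws at F_ST = 0.02; this creates the
  genotype-PC structure that the PC-adjusted regressions are meant to
  absorb. LD within a gene's variant block follows a Gaussian-copula
  AR(1) with ρ = 0.4 per haplotype; there is deliberately no LD across
  blocks. Genes sit on two synthetic chromosomes at 3 Mb spacing, with
  variants within ±100 kb of each TSS, so "within 1 Mb" and "beyond 5 Mb"
  windows are well defined without a genome build.
* **Counts.** For gene *j*, cell type *c*, nucleus of donor *d*:
  `log μ = b0_{cj} + pool_{p(d),j} + β_t,j t + (G_d − 1)(β_g,cj +
  1[c active] β_gt,j t) + chain_j(d) + u_{dj} + log L − mean(log L)`,
  with NB(μ, θ) sampling. Library size L is log-normal with cell-type
  specific means (detection tracks depth); pool batch effects are
  per-(pool, gene) normal perturbations; pseudotime t is donor age
  rescaled to [0, 1] plus nucleus-level jitter (trajectory construction
  itself is out of scope — pseudotime is an input to the dynamic model).
* **Ground truth.** Each gene receives a sharing pattern (null,
  shared-across-all, or specific to one cell type at per-allele log-mean
  effects 0.6/0.8 by default). Dynamic interaction effects are planted
  only in genes that carry a cis effect, and only in that pattern's
  active cell types — a dynamic eQTL is an eQTL whose effect varies, not
  a free-standing interaction. Trans chains pair a chr1 cis gene (forced
  shared, effect = a-path) with a chr2 target whose log mean receives
  b-path × (the cis gene's donor-level genetic + random-intercept
  component); there is no direct variant→trans path, so mediation should
  account for the whole trans effect at the donor level.
* **Synthetic GWAS.** Marginal effects follow the LD projection
  `β_v = effect · r(v, causal)` with SE = 1/√N and N(0, SE²) noise, where
  r is taken from the study genotypes *within 1 Mb of the causal variant*
  and set to zero beyond: population LD does not span the multi-megabase
  gene spacing, and a large GWAS would not inherit the study sample's
  correlation noise (using raw sample correlations at N_gwas-scale SEs
  produces wildly miscalibrated z-scores).

What the generator does **not** emulate: realistic LD beyond AR(1),
haplotype/read-level structure, ambient RNA, doublets, cell-type
misassignment, disease-status effects, or nonlinear pseudotime response.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
artifact of real single-nucleus data.

## Pseudobulk and normalization

Counts are summed per (donor, cell type); donors absent from a cell type
stay absent rather than being zero-filled. Per gene, a Poisson log-linear
model with a log total-depth offset and technical covariates (sample
pool, mitochondrial fraction by default) is fit by IRLS; Pearson
residuals `(y − μ̂)/√μ̂` are then centred and scaled to unit variance per
gene. The Poisson working model is a documented, swappable choice; the
re-standardization puts downstream effects on a standardized-expression
scale, coherent with the unit phenotypic variance assumed by the ABF
machinery. Genes nonzero in fewer than 20 donors (configurable) are
dropped per cell type. Hidden confounding is handled by PCA factors of
the residual matrix; the factor count is selected by maximizing the eGene
yield over a grid (ties to the smallest count). The demo grid is
{0, 2, 4} at 40 genes; at biobank scale the natural grid is much denser —
the selection rule, not the grid, is the point.

## Cis mapping and eGene calling

OLS per (gene, variant) with an intercept, top-5 genotype PCs and the
selected expression factors, implemented by residualizing both expression
and dosage on the covariates (Frisch–Waugh) and using
`df = n − n_covariates − 1`. Monomorphic variants are skipped; lead
variants break p-value ties by smaller position. The per-gene
multiple-testing correction inside the original mixed-model tooling is
not specified publicly, so eGene calling uses Bonferroni (by the gene's
cis variant count) on the lead p followed by BH across genes within cell
type — a conservative, standard stand-in.

## Fine-mapping

Single-causal-variant Wakefield ABFs with prior effect SD W = 0.15 on
standardized expression. PIPs are ABFs normalized within the gene; the
95% credible set is the smallest prefix of PIP-sorted variants with
cumulative PIP ≥ 0.95 (ten identical variants therefore yield a set of
size ten). MaxCPP takes, per variant, the maximum PIP over genes in whose
credible set it lies, else 0.

## Multivariate shrinkage and the composite test

The effect panel takes, per gene, the single variant with the smallest
p-value across cell types and that variant's estimate in every cell type
(missing cell types get β̂ = 0, SE = 1e6, which makes their likelihood
contribution vanish). The prior is a mixture of zero-centred multivariate
normals: a null matrix plus canonical structures (independent, one
singleton per cell type, equal effects, 0.5-correlated sharing) crossed
with an 8-point geometric scale grid spanning 0.1× the median |z| to 2×
the max |z| (converted to the β scale through the median SE). Only the
mixture weights are estimated, by EM on the marginal likelihood with
per-gene noise diag(SE²); residual correlations across cell types are set
to identity. A null-biased Dirichlet penalty (pseudo-count 10 on the null
component) resolves the near-flat direction between the exact null and
vanishingly small scales in favour of the conservative assignment — the
likelihood cannot distinguish a point mass from a normal with SD ≪ SE,
and without the penalty the EM parks weight arbitrarily across these
equivalent components.

Posteriors use the singular-safe conjugate form
`μ = U(U+S)⁻¹β̂`, `Σ = U − U(U+S)⁻¹U` per component, mixed by
responsibilities. The lfsr of an entry is the point mass at zero plus the
smaller tail probability; p = 1 − lfsr. The composite test multiplies
p over the "active" set and (1 − p) over the "zero" set, assuming
independence across cell types as stated — no joint-posterior correction
is attempted, and the 2^C arrangement probabilities sum to exactly 1
(enforced by a brute-force enumeration test). The specificity scan
evaluates each single-cell-type arrangement (plus optional family
arrangements via the at-least-one form) and reports the per-gene maximum;
the 0.5 threshold is applied after this maximization.

## Colocalization

Standard five-hypothesis ABF colocalization with priors p1 = p2 = 1e-4,
p12 = 1e-5 and W = 0.15 on both traits (traits are assumed standardized
to unit phenotypic variance). All hypothesis sums use log-sum-exp; H3 is
computed as `log(e^{Σa+Σb} − e^{Σab})` in log space, which is exact and
overflow-safe for |z| > 30. With a single variant H3 is degenerate and
flagged. Harmonization matches variants on position, flips signs for
swapped alleles and drops strand-ambiguous (A/T, C/G) variants.

## Dynamic eQTLs

The NB mixed model uses a log link with fixed effects (intercept,
pseudotime scaled to [0, 1], dosage, interaction, age/100, sex,
mitochondrial rate) and a donor random intercept. Library size enters as
a log offset by default (`libsize_as_covariate=True` reproduces the
covariate treatment; the offset is the standard NB convention). Fitting
is Laplace-approximated ML: an inner penalized IRLS solves for (β, u)
jointly given (σ², θ) via a Schur complement on the diagonal donor block;
the outer loop is Nelder–Mead over (log σ², log θ) after a coarse profile
over log θ — near-Poisson data make the θ profile extremely flat and a
plain simplex from a fixed start stalls well short of the optimum. Wald
SEs come from the Schur complement of the expected information at the
mode, conditional on the variance parameters (the same convention as the
standard GLMM tooling, which this implementation matches to <1% on shared
fits). σ² estimates at the lower clip are reported as exactly 0
(boundary). An adaptive Gauss–Hermite (7-node) evaluation of the marginal
likelihood is provided as a verification mode and agrees with the Laplace
value to well under 1%.

Calibration caveat: with few nuclei per donor and low counts the
interaction Wald test is anticonservative — a property of the
Wald/plug-in-variance test itself, shared by the reference mixed-model
implementations, not of this fitter (which matches them to <1% on shared
fits). Measured null rejection at nominal 5%: ~10% at 100 donors × 8
nuclei, ~6.4% at 120 × 12, ~4.7% at 150 × 15 (1,000-replicate runs). The
null-calibration check therefore runs 600 genes at 150 donors × 15
nuclei, a regime where the test is calibrated.

The dynamic scan tests each eGene's lead cis variant only (scanning all
cis variants is a trivial loop but multiplies cost); BH is applied within
cell type. The enrichment of colocalized genes among dynamic eGenes is
assessed by 100 rounds of sampling the same number of genes without
replacement from the tested universe; the resampled mean matches the
hypergeometric expectation and the SD serves as the reported SE.

## Trans mapping and mediation

The trans scan reuses the cis covariate machinery on candidate variants
(in practice: cis-eSNPs plus GWAS hits; any list can be supplied),
keeping pairs beyond 5 Mb or on different chromosomes, dropping MHC
variants (default interval chr6:25–34 Mb, configurable — no coordinates
are canonical) and genes with mappability < 0.8. Per (gene, cell type)
the minimum p gets `1 − (1 − p)^k` with k fixed at 1e5 (overridable),
computed via `expm1/log1p`; BH then runs across all genes and cell types.
A note on the Sidak constant: the exact value of `1 − (1 − 1e-7)^1e5` is
9.95016674586e-3 (30-digit arithmetic), which is what the implementation
returns.

Mediation uses the product-of-coefficients estimator with the Sobel SE;
LD r² is computed from the study genotypes (a reference panel is equally
valid; the study panel is what is available here). Note that the
pseudobulk mediator is a noisy measurement of the donor-level cis
component, so count-level chains show classical attenuation of b (and
hence of the estimated mediated proportion); the estimator itself is
unbiased when the mediator is observed directly, which the donor-level
linear simulation verifies. π1 over mediation p-values is reported as the
mediated-fraction summary when ≥ 50 tests are available.

## π0 / π1 estimation

`pi0(λ) = #{p > λ}/(m(1 − λ))` on the grid 0.05..0.95. The default
estimator is a precision-weighted average of pi0(λ) over λ ≥ 0.5 (weights
∝ √(m(1−λ))) — a stabilized form of Storey's fixed-λ estimator. Monte
Carlo evaluation (uniform null and a 30% alternative mixture, n = 5000)
shows it is essentially unbiased in both regimes with sampling SD ≈ 0.02,
versus ≈ 0.05 for the cubic-smoother extrapolation at the 0.95 endpoint;
the smoother remains available as `method="smoother"`. The tail average
is mildly conservative when alternative p-values have substantial mass
above 0.5 (very weak effects).

## Pipeline

Stages run in dependency order on in-memory state; each stochastic stage
derives its seed from the global seed and the stage name (CRC32-based,
< 2³¹). Output tables carry a `# stage=... config=<hash>` header; the
manifest records row counts and seeds only, so identical configurations
give byte-identical manifests. The demo configuration (150 donors, 40
genes, 3 cell types, 2 trans chains with b-path 0.9) is sized so that
every stage has signal to find in well under 15 minutes on one CPU.

## Known limitations

* Single-causal-variant fine-mapping and coloc; no conditional or
  multi-signal analysis.
* The shrinkage prior uses canonical covariances only (no data-driven
  PCA components) and diagonal residual correlation.
* The composite test inherits the stated independence assumption; with
  strongly correlated posteriors across cell types it is approximate.
* Mediation is the standard Sobel product form; the full estimator
  family from the weighted-regression literature is out of scope.
* The trans scan is restricted to supplied candidate variants, not
  genome-wide.
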