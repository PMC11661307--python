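# sneqtl

Single-nucleus eQTL analysis in Python: pseudobulk **cis-eQTL mapping**
with single-causal-variant fine-mapping, empirical-Bayes **multivariate
shrinkage** across cell types with a **composite cell-type-specificity
test**, Bayesian **colocalization** with GWAS signals, **dynamic
(pseudotime-interaction) eQTL** detection with a negative-binomial mixed
model, and **trans-eQTL mapping** with Sidak/BH correction and
**cis-mediation** analysis.

The package is aimed at statistical geneticists working with
population-scale single-nucleus RNA-seq cohorts (hundreds of genotyped
donors, millions of nuclei annotated to cell classes and subclasses) who
want a transparent, testable implementation of the full analysis chain.
A seeded synthetic-data generator emulates the statistical structure of
such cohorts — per-nucleus negative-binomial counts with donor random
intercepts, cell-type-structured cis effects, pseudotime-varying effects
and cis→trans mediation chains — so every stage can be validated against
known ground truth.

## The statistics

**Cis mapping.** Counts are summed per donor within each cell type,
converted to Pearson residuals under a per-gene Poisson model with a
log-depth offset and technical covariates, and standardized. For each
gene, every variant within 1 Mb of the TSS is tested by OLS of residual
expression on dosage with genotype PCs and PCA-derived hidden expression
factors as covariates (the factor count is chosen by the eGene yield over
a grid). eGenes: per-gene Bonferroni on the lead p-value, then BH across
genes at FDR 5%.

**Fine-mapping.** Wakefield approximate Bayes factors under a single
causal variant: `log ABF = ½ log(V/(V+W)) + ½ z² W/(V+W)` with `V = SE²`,
`W = 0.15²`; PIPs are normalized ABFs, the 95% credible set is the
smallest PIP-sorted prefix reaching 0.95, and MaxCPP annotates each
variant with its largest credible-set PIP across genes.

**Cell-type specificity.** Lead-variant effects `β̂` (genes × cell types)
are shrunk under a zero-centred mixture of multivariate normals over
canonical sharing structures fit by EM. With `p_i = 1 − lfsr_i` the
probability of a correctly-signed effect in cell type *i*, the composite
probability of the arrangement "effect in set 1, no effect in set 2" is

    ∏_{i∈set1} p_i × ∏_{i∈set2} (1 − p_i),

and "effect in at least one of set 1" is `1 − ∏(1 − p_i)`. A gene is
specific to a cell type when its arrangement probability exceeds 0.5.

**Colocalization.** Per-variant ABFs for two traits are summed over
single-causal configurations of the five hypotheses H0–H4 with priors
`p1 = p2 = 1e-4`, `p12 = 1e-5`; a shared signal is called at PP4 ≥ 0.5.

**Dynamic eQTLs.** Per-nucleus counts follow
`NB(exp(β₀ + β_t t + β_g G + β_gt G·t + covariates + u_donor + log L), θ)`
with `u_donor ~ N(0, σ²)`, fit by Laplace-approximated maximum likelihood;
the genotype×pseudotime interaction is tested by a Wald z.

**Trans-eQTLs and mediation.** Candidate variants are tested against genes
beyond 5 Mb (or on other chromosomes), excluding MHC variants and genes
with mappability < 0.8; per-gene minimum p-values get the Sidak correction
`1 − (1 − min p)^k` with `k = 1e5`, then BH across genes and cell types.
Hubs are variants with ≥ 3 significant targets. Cis-mediation uses the
product of coefficients `a·b` (SNP→cis gene, cis gene→trans gene given
the SNP) with a Sobel standard error, restricted to trans-eSNPs in LD
(r² ≥ 0.75) with a cis peak variant; Storey's π1 over the mediation
p-values estimates the mediated fraction.

## Worked example

```python
from sneqtl.simulate import SimConfig, simulate_genotypes, make_ground_truth, simulate_nuclei
from sneqtl import pseudobulk, cis, specificity as sp

cfg = SimConfig(n_donors=150, n_genes=30, n_cell_types=5, seed=42)
geno = simulate_genotypes(cfg)
truth = make_ground_truth(cfg)
nuclei = simulate_nuclei(cfg, geno, truth)

pb = pseudobulk.normalize(pseudobulk.aggregate(nuclei, level="subclass"))
table = cis.map_cis(pb, geno)
egenes = cis.egene_calling(table)
print(f"eGenes per cell type:\n{egenes.groupby('cell_type')['egene'].sum()}")

panel = sp.EffectPanel.from_table(table)
post = sp.posterior(panel, sp.fit_prior(panel))
scan = sp.specificity_scan(post)
print(scan[scan["specific"]].head(5).round(3))
```

prints

```
eGenes per cell type:
cell_type
Astro     6
ExcN     11
InhN      8
Micro    14
Oligo    11
Name: egene, dtype: int64
         arrangement  probability  specific
gene
GENE0001       Oligo        0.927      True
GENE0003       Micro        0.994      True
GENE0004        ExcN        0.992      True
GENE0006       Micro        1.000      True
GENE0008       Micro        0.999      True
```

Each row of the scan is a gene whose best arrangement is "effect in this
one cell type, none elsewhere" with the composite posterior probability
shown; `GENE0001`, for instance, was indeed planted as Oligo-specific
(per-allele effect 0.8 on the log mean) in the generator's ground truth.

## Command line

```bash
sneqtl run-all --outdir out --seed 1          # full pipeline on synthetic data
sneqtl cis --config my.yaml --outdir out      # one stage (plus dependencies)
```

`run-all` executes simulate → pseudobulk → cis → finemap → specificity →
coloc → dynamic → trans → mediate → enrich, writing per-stage TSVs (each
headed by the producing stage and configuration hash), the genotype VCF,
the MTX count matrix, ground truth JSON and a `manifest.json` with
per-stage row counts and derived seeds. Identical configurations produce
identical manifests.

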