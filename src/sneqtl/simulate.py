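"""Seeded synthetic cohort generator for single-nucleus eQTL analyses.

Generates genotypes, per-nucleus negative-binomial counts and metadata with
a known ground-truth effect configuration, emulating the statistical
structure of a large brain single-nucleus cohort at desk scale:

* dosages drawn from Hardy-Weinberg proportions, with optional two-
  subpopulation ancestry structure (Balding-Nichols) and AR(1) LD;
* per-nucleus counts ``NB(mean = exp(eta), size = theta)`` where ``eta``
  contains a gene/cell-type baseline, a per-allele cis effect restricted to
  the pattern's active cell types, pseudotime main and genotype-interaction
  terms, a donor random intercept, pool batch effects and a log library-
  size offset;
* pseudotime anchored on donor age (age rescaled to [0, 1] plus jitter),
  standing in for a maturation-trajectory coordinate;
* cis-to-trans mediation chains in which a variant drives a cis gene whose
  donor-level expression in turn drives a distant gene on another
  chromosome.

Everything is reproducible from ``SimConfig.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "SharingPattern",
    "TransChain",
    "GroundTruth",
    "GenotypeMatrix",
    "default_patterns",
    "simulate_genotypes",
    "make_ground_truth",
    "simulate_nuclei",
    "simulate_gwas",
]

_CELL_TYPE_NAMES = [
    "Astro", "Oligo", "Micro", "ExcN", "InhN", "OPC", "Endo", "Immune",
]

# gene spacing keeps cis windows (±1 Mb) free of neighbouring genes'
# variants and makes same-chromosome genes two or more slots apart
# unambiguously "beyond 5 Mb"
_GENE_SPACING = 3_000_000
_FIRST_TSS = 2_000_000
_VARIANT_SPAN = 200_000  # variants placed within ±100 kb of the TSS


@dataclass(frozen=True)
class SharingPattern:
    """Ground-truth cis-effect arrangement for one gene.

    ``label`` is one of ``specific``, ``shared_all``, ``shared_subset`` or
    ``null``; ``active_cell_types`` lists the cell types in which the
    per-allele effect ``effect_size`` (on the log mean) is non-zero.
    """

    label: str
    active_cell_types: frozenset[str]
    effect_size: float

    def __post_init__(self) -> None:
        if self.label not in {"specific", "shared_all", "shared_subset", "null"}:
            raise ValueError(f"unknown pattern label {self.label!r}")
        if self.label == "null":
            if self.effect_size != 0 or self.active_cell_types:
                raise ValueError("null pattern must have no active cell types "
                                 "and effect_size 0")
        else:
            if self.effect_size == 0:
                raise ValueError("non-null pattern needs effect_size != 0")
            if not self.active_cell_types:
                raise ValueError("non-null pattern needs a nonempty active set")


@dataclass(frozen=True)
class TransChain:
    """One cis->trans mediation triplet.

    The variant affects ``cis_gene`` with per-allele effect ``a_path``; the
    donor-level (genetic + random-intercept) log-expression of the cis gene
    feeds the log mean of ``trans_gene`` with slope ``b_path``. There is no
    direct variant->trans path.
    """

    variant: str
    cis_gene: str
    trans_gene: str
    a_path: float
    b_path: float


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults are a desk-scale rendition of a large snRNA-seq eQTL cohort:
    200 donors, 5 cell types, ~15 nuclei per donor per type, NB dispersion
    theta = 10 and a donor random-intercept SD of 0.3 on the log scale.
    """

    n_donors: int = 200
    n_genes: int = 60
    n_variants_per_gene: int = 10
    n_cell_types: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    nuclei_per_donor_mean: float = 15.0
    nuclei_nb_size: float = 10.0
    nb_dispersion: float = 10.0
    donor_re_sd: float = 0.3
    effect_patterns: list[SharingPattern] | None = None
    dynamic_fraction: float = 0.1
    dynamic_beta: float = 0.8
    trans_chains: int = 2
    trans_a_path: float = 1.0
    trans_b_path: float = 0.6
    seed: int = 0
    # nuisance structure
    ld_rho: float = 0.4
    ancestry_fst: float = 0.02
    n_pools: int = 4
    pool_effect_sd: float = 0.15
    pstime_main_sd: float = 0.2
    base_log_mean: float = -0.7
    base_log_sd: float = 0.5
    libsize_log_mean: float = np.log(2000.0)
    libsize_log_sd: float = 0.3
    class_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_genes", "n_variants_per_gene",
                     "n_cell_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must lie in (0, 0.5]")
        if not 0.0 <= self.dynamic_fraction <= 1.0:
            raise ValueError("dynamic_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.nuclei_nb_size <= 0:
            raise ValueError("NB size parameters must be positive")
        if self.donor_re_sd < 0:
            raise ValueError("donor_re_sd must be nonnegative")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def cell_types(self) -> list[str]:
        base = list(_CELL_TYPE_NAMES)
        while len(base) < self.n_cell_types:
            base.append(f"CT{len(base) + 1}")
        return base[: self.n_cell_types]


@dataclass
class GroundTruth:
    """Per-gene effect configuration used by parameter-recovery tests."""

    patterns: dict[str, SharingPattern]
    dynamic_beta: dict[str, float]
    chains: list[TransChain]

    @property
    def dynamic_genes(self) -> set[str]:
        return {g for g, b in self.dynamic_beta.items() if b != 0.0}


@dataclass
class GenotypeMatrix:
    """Donor x variant dosage matrix with coordinates and ancestry PCs."""

    dosages: np.ndarray  # (n_donors, n_variants) values in {0, 1, 2}
    donors: list[str]
    variants: pd.DataFrame  # variant, chrom, pos, ref, alt, maf, cis_gene
    genes: pd.DataFrame  # gene, chrom, tss, strand
    population: np.ndarray | None = None
    _pcs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_donors(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, variant: str) -> int:
        idx = self.variants.index[self.variants["variant"] == variant]
        if len(idx) == 0:
            raise KeyError(f"variant {variant!r} not in genotype matrix")
        return int(idx[0])

    def pcs(self, n_components: int = 5) -> np.ndarray:
        """Top genotype principal components (donors x k), centred SVD."""
        if self._pcs is None or self._pcs.shape[1] < n_components:
            x = self.dosages.astype(float)
            x = x - x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            u, s, _ = np.linalg.svd(x / sd, full_matrices=False)
            self._pcs = u * s
        return self._pcs[:, :n_components]


def default_patterns(cell_types: list[str]) -> list[SharingPattern]:
    """Default mix: null, shared-across-all, and one specific pattern per
    cell type (per-allele log-mean effects 0.6 shared, 0.8 specific)."""
    pats = [
        SharingPattern("null", frozenset(), 0.0),
        SharingPattern("shared_all", frozenset(cell_types), 0.6),
    ]
    pats += [
        SharingPattern("specific", frozenset({ct}), 0.8) for ct in cell_types
    ]
    return pats


def _gene_layout(config: SimConfig) -> pd.DataFrame:
    n = config.n_genes
    n_chr1 = (n + 1) // 2
    rows = []
    for i in range(n):
        chrom = "chr1" if i < n_chr1 else "chr2"
        slot = i if i < n_chr1 else i - n_chr1
        rows.append({
            "gene": f"GENE{i + 1:04d}",
            "chrom": chrom,
            "tss": _FIRST_TSS + slot * _GENE_SPACING,
            "strand": "+",
        })
    return pd.DataFrame(rows)


def _variant_layout(config: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    m = config.n_variants_per_gene
    offsets = (
        np.linspace(-_VARIANT_SPAN / 2, _VARIANT_SPAN / 2, m).astype(int)
        if m > 1
        else np.array([0])
    )
    rows = []
    for _, g in genes.iterrows():
        for j, off in enumerate(offsets):
            rows.append({
                "variant": f"{g.gene}_v{j + 1}",
                "chrom": g.chrom,
                "pos": int(g.tss + off),
                "ref": "A",
                "alt": "G",
                "cis_gene": g.gene,
            })
    return pd.DataFrame(rows)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw dosages from Hardy-Weinberg proportions at per-variant MAFs.

    MAFs are uniform on ``config.maf_range``. With ``ancestry_fst > 0`` the
    cohort is a 50/50 mix of two subpopulations whose variant frequencies
    are Balding-Nichols perturbations of the target MAF, creating genotype
    PC structure. With ``ld_rho > 0`` alleles on each of the two haplotypes
    follow a Gaussian-copula AR(1) chain across the variants of a gene, so
    marginal Hardy-Weinberg proportions are preserved while neighbouring
    variants are correlated.
    """
    rng = np.random.default_rng([config.seed, 11])
    genes = _gene_layout(config)
    variants = _variant_layout(config, genes)
    n_var = len(variants)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_var)

    population = rng.integers(0, 2, size=config.n_donors)
    if config.ancestry_fst > 0:
        f = config.ancestry_fst
        a = maf * (1 - f) / f
        b = (1 - maf) * (1 - f) / f
        pop_freq = np.stack([rng.beta(a, b), rng.beta(a, b)])  # (2, n_var)
        pop_freq = np.clip(pop_freq, 1e-4, 1 - 1e-4)
    else:
        pop_freq = np.stack([maf, maf])

    freq = pop_freq[population]  # (n_donors, n_var)
    if config.ld_rho > 0 and config.n_variants_per_gene > 1:
        rho = config.ld_rho
        m = config.n_variants_per_gene
        dosage = np.zeros((config.n_donors, n_var), dtype=np.int8)
        thresh = norm.ppf(freq)
        for _ in range(2):  # two haplotypes
            z = rng.standard_normal((config.n_donors, n_var))
            zc = np.empty_like(z)
            for g in range(config.n_genes):
                sl = slice(g * m, (g + 1) * m)
                block = z[:, sl]
                out = np.empty_like(block)
                out[:, 0] = block[:, 0]
                for j in range(1, m):
                    out[:, j] = rho * out[:, j - 1] + np.sqrt(1 - rho**2) * block[:, j]
                zc[:, sl] = out
            dosage += (zc < thresh).astype(np.int8)
    else:
        dosage = rng.binomial(2, freq).astype(np.int8)

    variants = variants.assign(maf=maf)
    donors = [f"D{i + 1:04d}" for i in range(config.n_donors)]
    return GenotypeMatrix(
        dosages=dosage,
        donors=donors,
        variants=variants,
        genes=genes,
        population=population,
    )


def make_ground_truth(config: SimConfig) -> GroundTruth:
    """Assign each gene a sharing pattern, dynamic status and trans chains.

    Trans chains pair a cis gene on chr1 (forced ``shared_all`` with effect
    ``trans_a_path``) with a target gene on chr2 (forced ``null`` for its
    own local variants); the mediating variant is the cis gene's central
    variant.
    """
    rng = np.random.default_rng([config.seed, 22])
    cell_types = config.cell_types
    patterns = config.effect_patterns or default_patterns(cell_types)
    for p in patterns:
        unknown = p.active_cell_types - set(cell_types)
        if unknown:
            raise ValueError(f"pattern references unknown cell types {unknown}")

    genes = _gene_layout(config)
    gene_ids = genes["gene"].tolist()
    chr1_genes = genes.loc[genes.chrom == "chr1", "gene"].tolist()
    chr2_genes = genes.loc[genes.chrom == "chr2", "gene"].tolist()
    if config.trans_chains > min(len(chr1_genes), len(chr2_genes)):
        raise ValueError(
            f"trans_chains={config.trans_chains} exceeds available gene pairs"
        )

    assignment = {
        g: patterns[k]
        for g, k in zip(gene_ids, rng.integers(0, len(patterns), len(gene_ids)))
    }

    chains: list[TransChain] = []
    cis_pool = rng.permutation(chr1_genes)[: config.trans_chains]
    trans_pool = rng.permutation(chr2_genes)[: config.trans_chains]
    mid = (config.n_variants_per_gene + 1) // 2
    for cis_g, trans_g in zip(cis_pool, trans_pool):
        assignment[cis_g] = SharingPattern(
            "shared_all", frozenset(cell_types), config.trans_a_path
        )
        assignment[trans_g] = SharingPattern("null", frozenset(), 0.0)
        chains.append(TransChain(
            variant=f"{cis_g}_v{mid}",
            cis_gene=cis_g,
            trans_gene=trans_g,
            a_path=config.trans_a_path,
            b_path=config.trans_b_path,
        ))

    # dynamic eQTLs are eQTLs whose effect varies along pseudotime, so the
    # interaction is planted only in genes that carry a cis effect at all
    n_dynamic = int(round(config.dynamic_fraction * config.n_genes))
    chain_genes = {c.trans_gene for c in chains}
    eligible = [g for g in gene_ids
                if g not in chain_genes and assignment[g].label != "null"]
    dynamic = set(rng.permutation(eligible)[:n_dynamic])
    dynamic_beta = {
        g: (config.dynamic_beta if g in dynamic else 0.0) for g in gene_ids
    }
    return GroundTruth(patterns=assignment, dynamic_beta=dynamic_beta,
                       chains=chains)


def simulate_nuclei(
    config: SimConfig,
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
) -> ad.AnnData:
    """Draw per-nucleus counts and metadata for the whole cohort.

    Counts for gene j in a nucleus of donor d, cell type c are NB with

    ``log mu = b0[c,j] + pool[j] + bt[j]*t
               + (G-1)*(bg[c,j] + 1[c active]*bgt[j]*t)
               + b_chain*m_d + u[d,j] + log L - mean(log L)``

    where ``t`` is nucleus pseudotime, ``G`` the dosage at the gene's
    central cis variant, ``u`` the donor random intercept and ``L`` the
    latent library-size factor. ``m_d`` is the mediating cis gene's donor
    component for trans-chain targets. Dispersion is ``config.nb_dispersion``
    (theta; variance mu + mu^2/theta).

    Returns an :class:`anndata.AnnData` with sparse integer counts and
    complete nucleus metadata (donor, cell class/subclass, pseudotime,
    mitochondrial fraction, pool, sex, age).
    """
    if set(genotypes.genes["gene"]) != set(truth.patterns):
        raise ValueError("genotypes and ground truth cover different genes")
    rng = np.random.default_rng([config.seed, 33])
    cell_types = config.cell_types
    genes = genotypes.genes
    gene_ids = genes["gene"].tolist()
    n_genes = len(gene_ids)
    n_donors = config.n_donors
    theta = config.nb_dispersion

    # donor-level attributes
    age = rng.uniform(0.0, 97.0, n_donors)
    pstime_donor = age / 97.0
    sex = rng.integers(0, 2, n_donors)
    pool = rng.integers(0, config.n_pools, n_donors)
    u_donor = rng.normal(0.0, config.donor_re_sd, size=(n_donors, n_genes))

    # per-gene / per-cell-type fixed structure
    b0 = rng.normal(config.base_log_mean, config.base_log_sd, size=n_genes)
    ct_shift = rng.normal(0.0, 0.3, size=(len(cell_types), n_genes))
    pool_eff = rng.normal(0.0, config.pool_effect_sd,
                          size=(config.n_pools, n_genes))
    beta_t = rng.normal(0.0, config.pstime_main_sd, size=n_genes)
    beta_gt = np.array([truth.dynamic_beta[g] for g in gene_ids])

    beta_g = np.zeros((len(cell_types), n_genes))
    active_mask = np.zeros((len(cell_types), n_genes))
    for j, g in enumerate(gene_ids):
        pat = truth.patterns[g]
        for i, ct in enumerate(cell_types):
            if ct in pat.active_cell_types:
                beta_g[i, j] = pat.effect_size
                active_mask[i, j] = 1.0

    # dosage at each gene's central cis variant
    mid = (config.n_variants_per_gene + 1) // 2
    lead_idx = [genotypes.variant_index(f"{g}_v{mid}") for g in gene_ids]
    G = genotypes.dosages[:, lead_idx].astype(float)  # donors x genes

    # trans-chain input: donor-level component of the mediating cis gene
    chain_input = np.zeros((n_donors, n_genes))
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    for ch in truth.chains:
        jc, jt = gene_pos[ch.cis_gene], gene_pos[ch.trans_gene]
        m_d = ch.a_path * (G[:, jc] - 1.0) + u_donor[:, jc]
        chain_input[:, jt] = ch.b_path * m_d

    class_map = config.class_map or {}

    obs_parts, count_parts = [], []
    for ci, ct in enumerate(cell_types):
        n_nuc = rng.negative_binomial(
            config.nuclei_nb_size,
            config.nuclei_nb_size / (config.nuclei_nb_size
                                     + config.nuclei_per_donor_mean),
            size=n_donors,
        )
        n_nuc = np.maximum(n_nuc, 1)  # every donor contributes
        donor_idx = np.repeat(np.arange(n_donors), n_nuc)
        n_total = donor_idx.size

        t = np.clip(pstime_donor[donor_idx]
                    + rng.normal(0, 0.03, n_total), 0.0, 1.0)
        log_l = rng.normal(config.libsize_log_mean + 0.1 * ci,
                           config.libsize_log_sd, n_total)
        log_l_c = log_l - (config.libsize_log_mean + 0.1 * ci)
        mito = np.clip(rng.beta(2.0, 38.0, n_total), 0.0, 1.0)

        eta = (
            b0[None, :] + ct_shift[ci][None, :]
            + pool_eff[pool[donor_idx]]
            + beta_t[None, :] * t[:, None]
            + (G[donor_idx] - 1.0)
            * (beta_g[ci][None, :]
               + active_mask[ci][None, :] * beta_gt[None, :] * t[:, None])
            + chain_input[donor_idx]
            + u_donor[donor_idx]
            + log_l_c[:, None]
        )
        mu = np.exp(eta)
        counts = rng.negative_binomial(theta, theta / (theta + mu))
        count_parts.append(sparse.csr_matrix(counts))

        obs_parts.append(pd.DataFrame({
            "donor": np.array(genotypes.donors)[donor_idx],
            "cell_subclass": ct,
            "cell_class": class_map.get(ct, ct),
            "pseudotime": t,
            "mito_frac": mito,
            "pool": [f"pool{p + 1}" for p in pool[donor_idx]],
            "sex": np.where(sex[donor_idx] == 0, "F", "M"),
            "age": age[donor_idx],
        }))

    obs = pd.concat(obs_parts, ignore_index=True)
    obs.index = [f"nucleus{i + 1:07d}" for i in range(len(obs))]
    x = sparse.vstack(count_parts).tocsr()
    var = genes.set_index("gene")[["chrom", "tss", "strand"]].copy()
    adata = ad.AnnData(X=x, obs=obs, var=var)
    adata.obs["total_counts"] = np.asarray(x.sum(axis=1)).ravel()
    return adata


def simulate_gwas(
    genotypes: GenotypeMatrix,
    causal_variant: str,
    effect: float = 0.3,
    n_gwas: int = 50_000,
    seed: int = 0,
    variants: list[str] | None = None,
    ld_window: float = 1e6,
) -> pd.DataFrame:
    """Synthetic GWAS summary statistics sharing one causal variant.

    Marginal effects on a standardized trait follow the usual LD
    projection: ``beta_v = effect * r(v, causal) + e_v`` with sampling
    noise ``e_v ~ N(0, 1/n_gwas)`` and ``SE = 1/sqrt(n_gwas)``. ``r`` is
    the dosage correlation in the study genotypes for variants within
    ``ld_window`` of the causal variant and 0 beyond it — population LD
    does not extend across the multi-megabase gene spacing, and a large
    GWAS would not inherit the study sample's correlation noise. Pass
    ``effect = 0`` for a null trait.
    """
    rng = np.random.default_rng([seed, 44])
    tab = genotypes.variants
    if variants is not None:
        tab = tab[tab["variant"].isin(variants)]
    dos = genotypes.dosages.astype(float)
    ci = genotypes.variant_index(causal_variant)
    g_c = dos[:, ci]
    c_chrom = genotypes.variants["chrom"].iloc[ci]
    c_pos = genotypes.variants["pos"].iloc[ci]
    se = 1.0 / np.sqrt(n_gwas)
    rows = []
    for j, row in tab.iterrows():
        g = dos[:, j]
        r = 0.0
        in_ld = row.chrom == c_chrom and abs(row.pos - c_pos) <= ld_window
        if in_ld and g.std() > 0 and g_c.std() > 0:
            r = float(np.corrcoef(g, g_c)[0, 1])
        beta = effect * r + rng.normal(0.0, se)
        rows.append((row.variant, row.chrom, int(row.pos), row.ref, row.alt,
                     beta, se, n_gwas))
    return pd.DataFrame(rows, columns=[
        "variant", "chrom", "pos", "ref", "alt", "beta", "se", "n"])
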