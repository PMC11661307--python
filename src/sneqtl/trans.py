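"""Trans-eQTL mapping, hub detection and cis-mediation analysis.

Candidate variants (cis-eSNPs plus GWAS-significant variants) are tested
against all genes farther than 5 Mb away or on another chromosome, with
the same covariate adjustment as cis mapping. Genes with mappability
below 0.8 and variants inside the MHC interval are excluded. Multiple
testing is two-stage: a Sidak correction of each gene's minimum p-value
with k = 1e5, then Benjamini-Hochberg across all genes and cell types.
Hubs are variants with at least three significant target genes.

Cis-mediation follows the product-of-coefficients strategy: for a
trans-eSNP in high LD (r^2 >= 0.75) with the peak cis variant of a
nearby gene, the indirect effect is a*b where a is the SNP -> cis-gene
effect and b the cis-gene -> trans-gene effect adjusted for the SNP,
with a Sobel standard error; Storey's pi1 over the mediation p-values
estimates the fraction of trans signals consistent with cis-mediation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import qvalue
from .cis import _residualize
from .pseudobulk import PseudobulkExpression
from .simulate import GenotypeMatrix

__all__ = [
    "map_trans",
    "sidak_correct",
    "study_fdr",
    "find_hubs",
    "mediate",
    "ld_r2",
    "TransHub",
    "DEFAULT_MHC",
]

DEFAULT_MHC = ("chr6", 25_000_000, 34_000_000)  # GRCh38 extended MHC
DEFAULT_SIDAK_K = 1e5


def sidak_correct(p_vector: np.ndarray, k: float = DEFAULT_SIDAK_K) -> float:
    """Sidak-corrected minimum p-value: ``1 - (1 - min(p))^k``.

    Computed as ``-expm1(k * log1p(-min p))`` for accuracy at small p.
    """
    p = np.asarray(p_vector, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pmin = float(p.min())
    if pmin == 0.0:
        return 0.0
    if pmin == 1.0:
        return 1.0
    return float(-np.expm1(k * np.log1p(-pmin)))


def study_fdr(sidak_ps: pd.Series | np.ndarray) -> np.ndarray:
    """BH q-values pooled across all genes and cell types."""
    p = np.asarray(sidak_ps, dtype=float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _in_mhc(variants: pd.DataFrame, mhc: tuple[str, int, int]) -> np.ndarray:
    chrom, start, end = mhc
    return ((variants["chrom"] == chrom)
            & (variants["pos"] >= start)
            & (variants["pos"] <= end)).to_numpy()


def map_trans(
    pb: PseudobulkExpression,
    genotypes: GenotypeMatrix,
    candidate_variants: list[str],
    mappability: dict[str, float] | None = None,
    min_distance: float = 5e6,
    mappability_min: float = 0.8,
    mhc: tuple[str, int, int] = DEFAULT_MHC,
    n_pcs: int = 5,
    sidak_k: float = DEFAULT_SIDAK_K,
    fdr: float = 0.05,
    extra_covariates: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Trans scan over candidate variants with two-stage correction.

    Returns one row per retained (gene, variant, cell type) pair with the
    regression estimate and, per (gene, cell type), the Sidak-corrected
    minimum p and the study-wide BH q (on columns ``p_sidak`` / ``q``,
    repeated within the group). Pairs closer than ``min_distance`` on the
    same chromosome are excluded, as are MHC variants and genes with
    mappability below ``mappability_min``.
    """
    if not pb.residuals:
        raise ValueError("pseudobulk has no normalized residuals")
    var_tab = genotypes.variants.set_index("variant")
    missing = [v for v in candidate_variants if v not in var_tab.index]
    if missing:
        raise KeyError(f"candidate variants absent from genotypes: "
                       f"{missing[:5]}")
    cand = var_tab.loc[candidate_variants].reset_index()
    cand = cand[~_in_mhc(cand, mhc)]
    gene_info = pb.genes.set_index("gene")
    donor_pos = {d: i for i, d in enumerate(genotypes.donors)}
    pcs_all = genotypes.pcs(n_pcs) if n_pcs > 0 else None

    records = []
    for ct, res in pb.residuals.items():
        donors = [d for d in res.columns if d in donor_pos]
        didx = np.array([donor_pos[d] for d in donors])
        covs = [np.ones((len(donors), 1))]
        if pcs_all is not None:
            covs.append(pcs_all[didx])
        if extra_covariates and ct in extra_covariates:
            covs.append(np.asarray(extra_covariates[ct], dtype=float))
        covmat = np.column_stack(covs)
        n, p_cov = covmat.shape
        df = n - p_cov - 1
        vidx = np.array([genotypes.variant_index(v) for v in cand["variant"]])
        dos = genotypes.dosages[didx][:, vidx].astype(float)
        poly = dos.std(axis=0) > 0
        g_resid = _residualize(dos, covmat)
        y_resid = _residualize(res[donors].to_numpy().T, covmat)

        for gi, gene in enumerate(res.index):
            if mappability is not None and \
                    mappability.get(gene, 1.0) < mappability_min:
                continue
            info = gene_info.loc[gene]
            far = ((cand["chrom"] != info["chrom"])
                   | (np.abs(cand["pos"] - info["tss"]) > min_distance)
                   ).to_numpy()
            sel = np.flatnonzero(far & poly)
            if sel.size == 0:
                continue
            g = g_resid[:, sel]
            y = y_resid[:, gi]
            gg = np.einsum("ij,ij->j", g, g)
            beta = (g.T @ y) / gg
            rss = np.maximum(y @ y - beta**2 * gg, 0.0)
            se = np.sqrt(np.maximum(rss / df / gg, 1e-300))
            pv = np.clip(2 * stats.t.sf(np.abs(beta / se), df),
                         np.finfo(float).tiny, 1.0)
            psidak = sidak_correct(pv, k=sidak_k)
            for k_, ci in enumerate(sel):
                records.append((
                    gene, cand["variant"].iat[ci], cand["chrom"].iat[ci],
                    int(cand["pos"].iat[ci]), ct,
                    beta[k_], se[k_], pv[k_], psidak,
                ))

    out = pd.DataFrame(records, columns=[
        "gene", "variant", "chrom", "pos", "cell_type",
        "beta", "se", "p", "p_sidak",
    ])
    if out.empty:
        return out.assign(q=pd.Series(dtype=float),
                          significant=pd.Series(dtype=bool))
    per_gene = (out.groupby(["gene", "cell_type"])["p_sidak"].first()
                .reset_index())
    per_gene["q"] = study_fdr(per_gene["p_sidak"])
    out = out.merge(per_gene[["gene", "cell_type", "q"]],
                    on=["gene", "cell_type"])
    # a gene's trans-eQTL is its best pair within a significant gene
    out["significant"] = out["q"] <= fdr
    return out


@dataclass
class TransHub:
    """A variant associated in trans with >= min_targets genes."""

    variant: str
    cell_type: str
    targets: list[str]


def find_hubs(results: pd.DataFrame, min_targets: int = 3,
              fdr: float = 0.05) -> list[TransHub]:
    """Group study-wide significant trans pairs into regulatory hubs.

    For each significant (gene, cell type), the best variant (minimum raw
    p) is taken as that gene's trans-eSNP; variants regulating at least
    ``min_targets`` genes within a cell type form hubs.
    """
    sig = results[results["significant"]]
    if sig.empty:
        return []
    best = (sig.sort_values(["gene", "cell_type", "p", "pos"],
                            kind="mergesort")
            .groupby(["gene", "cell_type"], sort=False).head(1))
    hubs = []
    for (v, ct), grp in best.groupby(["variant", "cell_type"], sort=True):
        genes = sorted(grp["gene"].unique())
        if len(genes) >= min_targets:
            hubs.append(TransHub(variant=v, cell_type=ct, targets=genes))
    return hubs


def ld_r2(genotypes: GenotypeMatrix, v1: str, v2: str) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    g1 = genotypes.dosages[:, genotypes.variant_index(v1)].astype(float)
    g2 = genotypes.dosages[:, genotypes.variant_index(v2)].astype(float)
    if g1.std() == 0 or g2.std() == 0:
        raise ValueError("monomorphic variant in LD computation")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r**2)


def _ols(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and SEs from OLS with an intercept prepended."""
    x = np.column_stack([np.ones(len(y)), design])
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(x.T @ x)
    return beta[1:], np.sqrt(np.diag(cov))[1:]


def mediate(
    trans_results: pd.DataFrame,
    cis_egenes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pb: PseudobulkExpression,
    ld_threshold: float = 0.75,
    cis_window: float = 1e6,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Product-of-coefficients mediation of trans signals by cis genes.

    For each significant trans pair, candidate mediators are cis eGenes
    whose peak variant lies within ``cis_window`` of the trans-eSNP and is
    in LD (r^2 >= ``ld_threshold``) with it. Then, on standardized
    pseudobulk residuals: ``a`` = SNP -> mediator slope, ``b`` = mediator
    -> trans gene slope adjusting for the SNP, indirect = a*b with Sobel
    SE ``sqrt(b^2 SE_a^2 + a^2 SE_b^2)``; total = SNP -> trans-gene slope;
    proportion mediated = indirect / total. BH across all tests; Storey's
    pi1 of the mediation p-values is attached as ``pi1`` metadata.
    """
    sig = trans_results[trans_results["significant"]]
    best = (sig.sort_values(["gene", "cell_type", "p", "pos"],
                            kind="mergesort")
            .groupby(["gene", "cell_type"], sort=False).head(1))
    peaks = cis_egenes[cis_egenes["egene"]] if "egene" in cis_egenes \
        else cis_egenes
    var_tab = genotypes.variants.set_index("variant")
    donor_pos = {d: i for i, d in enumerate(genotypes.donors)}

    rows = []
    for _, tr in best.iterrows():
        ct = tr["cell_type"]
        res = pb.residuals.get(ct)
        if res is None or tr["gene"] not in res.index:
            continue
        snp_chrom, snp_pos = tr["chrom"], tr["pos"]
        cands = peaks[peaks["cell_type"] == ct]
        for _, cis_row in cands.iterrows():
            mediator, peak_var = cis_row["gene"], cis_row["variant"]
            if mediator == tr["gene"] or mediator not in res.index:
                continue
            pv = var_tab.loc[peak_var]
            if pv["chrom"] != snp_chrom or abs(pv["pos"] - snp_pos) > cis_window:
                continue
            try:
                r2 = ld_r2(genotypes, tr["variant"], peak_var)
            except ValueError:
                continue
            if r2 < ld_threshold:
                continue
            donors = [d for d in res.columns if d in donor_pos]
            didx = np.array([donor_pos[d] for d in donors])
            snp = genotypes.dosages[
                didx, genotypes.variant_index(tr["variant"])].astype(float)
            med = res.loc[mediator, donors].to_numpy()
            trg = res.loc[tr["gene"], donors].to_numpy()
            (a,), (se_a,) = _ols(med, snp[:, None])
            bcoef, se_b_v = _ols(trg, np.column_stack([med, snp]))
            b, se_b = bcoef[0], se_b_v[0]
            (total,), _ = _ols(trg, snp[:, None])
            indirect = a * b
            sobel_se = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
            z = indirect / sobel_se if sobel_se > 0 else 0.0
            rows.append({
                "trans_snp": tr["variant"], "cis_gene": mediator,
                "trans_gene": tr["gene"], "cell_type": ct, "ld_r2": r2,
                "a": a, "se_a": se_a, "b": b, "se_b": se_b,
                "indirect": indirect, "sobel_se": sobel_se, "z": z,
                "p": 2 * stats.norm.sf(abs(z)),
                "total": total,
                "prop_mediated": indirect / total if total != 0 else np.nan,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        out.attrs["pi1"] = np.nan
        return out
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["significant"] = out["q"] <= fdr
    out.attrs["pi1"] = qvalue.pi1(out["p"].to_numpy()) \
        if len(out) >= 50 else np.nan
    return out
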