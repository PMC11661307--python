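"""Cis-eQTL mapping and downstream summaries.

Per cell type, standardized pseudobulk residuals are regressed on variant
dosage for every variant within the cis window (default 1 Mb of the TSS),
adjusting for genotype principal components and any selected hidden
expression factors. eGenes are called by Bonferroni adjustment of the lead
p-value within each gene followed by Benjamini-Hochberg across genes.
Single-causal-variant fine-mapping uses Wakefield approximate Bayes
factors, yielding per-variant posterior inclusion probabilities, 95%
credible sets and the per-variant MaxCPP annotation. Replication between
datasets is summarized by Storey's pi1, and positional enrichment of
open-chromatin regions around lead variants by 10-kb bin densities over a
2 Mb window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import qvalue
from .pseudobulk import PseudobulkExpression
from .simulate import GenotypeMatrix

__all__ = [
    "map_cis",
    "egene_calling",
    "finemap_abf",
    "maxcpp",
    "pi1_replication",
    "ocr_bin_density",
    "BinDensityProfile",
]

DEFAULT_PRIOR_SD = 0.15  # prior effect SD on standardized expression


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Project out covariate columns (including intercept)."""
    q, _ = np.linalg.qr(covs)
    return y - q @ (q.T @ y)


def map_cis(
    pb: PseudobulkExpression,
    genotypes: GenotypeMatrix,
    window_bp: float = 1e6,
    n_pcs: int = 5,
    n_min: int = 30,
    cell_types: list[str] | None = None,
    extra_covariates: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per (gene, variant, cell type) linear cis-eQTL scan.

    Expression residuals and dosages are both residualized on an intercept,
    the top ``n_pcs`` genotype PCs and any ``extra_covariates`` (per cell
    type, donors x k), after which per-variant slopes, standard errors and
    two-sided t-test p-values follow from simple regression with degrees of
    freedom ``n - n_covariates - 1``. Monomorphic variants are skipped;
    genes observed in fewer than ``n_min`` donors are skipped for that cell
    type. Lead variant per gene = smallest p, ties broken by smaller
    position.
    """
    if not pb.residuals:
        raise ValueError("pseudobulk has no normalized residuals; "
                         "run pseudobulk.normalize first")
    gene_info = pb.genes.set_index("gene")
    donor_pos = {d: i for i, d in enumerate(genotypes.donors)}
    pcs_all = genotypes.pcs(n_pcs) if n_pcs > 0 else None
    var_tab = genotypes.variants

    records = []
    for ct in cell_types or list(pb.residuals):
        res = pb.residuals[ct]
        donors = [d for d in res.columns if d in donor_pos]
        if len(donors) < n_min:
            continue
        didx = np.array([donor_pos[d] for d in donors])
        y_all = res[donors].to_numpy()
        covs = [np.ones((len(donors), 1))]
        if pcs_all is not None:
            covs.append(pcs_all[didx])
        if extra_covariates and ct in extra_covariates:
            extra = np.asarray(extra_covariates[ct], dtype=float)
            if extra.shape[0] != len(donors):
                raise ValueError(f"{ct}: extra covariates rows != donors")
            covs.append(extra)
        covmat = np.column_stack(covs)
        p_cov = covmat.shape[1]
        dos = genotypes.dosages[didx].astype(float)
        g_resid = _residualize(dos, covmat)
        y_resid = _residualize(y_all.T, covmat)  # donors x genes
        n = len(donors)
        df = n - p_cov - 1
        if df < 1:
            raise ValueError(f"{ct}: not enough donors for covariate count")

        for gi, gene in enumerate(res.index):
            if gene not in gene_info.index:
                continue
            info = gene_info.loc[gene]
            cis_mask = (
                (var_tab["chrom"] == info["chrom"])
                & (np.abs(var_tab["pos"] - info["tss"]) <= window_bp)
            ).to_numpy()
            vidx = np.flatnonzero(cis_mask)
            if vidx.size == 0:
                continue
            raw = dos[:, vidx]
            poly = raw.std(axis=0) > 0
            vidx = vidx[poly]
            if vidx.size == 0:
                continue
            g = g_resid[:, vidx]
            y = y_resid[:, gi]
            gg = np.einsum("ij,ij->j", g, g)
            gy = g.T @ y
            beta = gy / gg
            rss = y @ y - beta**2 * gg
            rss = np.maximum(rss, 0.0)
            sigma2 = rss / df
            se = np.sqrt(np.maximum(sigma2 / gg, 1e-300))
            tstat = beta / se
            pval = 2 * stats.t.sf(np.abs(tstat), df)
            pval = np.clip(pval, np.finfo(float).tiny, 1.0)
            af = raw[:, poly].mean(axis=0) / 2.0
            sub = var_tab.iloc[vidx]
            for k in range(vidx.size):
                records.append((
                    gene, sub["variant"].iat[k], sub["chrom"].iat[k],
                    int(sub["pos"].iat[k]), ct, beta[k], se[k], pval[k],
                    float(min(af[k], 1 - af[k])), n,
                ))

    table = pd.DataFrame(records, columns=[
        "gene", "variant", "chrom", "pos", "cell_type",
        "beta", "se", "p", "maf", "n",
    ])
    if table.empty:
        return table.assign(is_lead=pd.Series(dtype=bool))
    # lead per (cell_type, gene): min p, ties -> smaller position
    order = table.sort_values(["cell_type", "gene", "p", "pos"],
                              kind="mergesort")
    lead_rows = order.groupby(["cell_type", "gene"], sort=False).head(1).index
    table["is_lead"] = False
    table.loc[lead_rows, "is_lead"] = True
    return table


def egene_calling(table: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Call eGenes from a cis scan.

    The lead p-value of each gene is Bonferroni-adjusted by that gene's
    number of tested cis variants, then Benjamini-Hochberg is applied
    across genes within each cell type; eGene = q <= ``fdr``.
    """
    if table.empty:
        raise ValueError("empty eQTL table")
    grp = table.groupby(["cell_type", "gene"], sort=True)
    summary = grp.agg(n_variants=("p", "size")).reset_index()
    leads = (table[table["is_lead"]]
             .set_index(["cell_type", "gene"])[["variant", "p", "pos"]])
    summary = summary.join(leads, on=["cell_type", "gene"])
    summary["p_bonf"] = np.minimum(summary["p"] * summary["n_variants"], 1.0)
    summary["q"] = np.nan
    for ct, idx in summary.groupby("cell_type").groups.items():
        _, qv, _, _ = multipletests(summary.loc[idx, "p_bonf"],
                                    method="fdr_bh")
        summary.loc[idx, "q"] = qv
    summary["egene"] = summary["q"] <= fdr
    return summary.rename(columns={"p": "p_lead"})


def finemap_abf(
    gene_table: pd.DataFrame,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> pd.DataFrame:
    """Single-causal-variant fine-mapping via Wakefield ABFs.

    ``log ABF_v = 0.5 log(V/(V+W)) + 0.5 z^2 W/(V+W)`` with ``V = SE^2``,
    ``W = prior_sd^2``; PIPs are the normalized ABFs and the 95% credible
    set is the smallest prefix of PIP-sorted variants whose cumulative PIP
    reaches 0.95.
    """
    if gene_table.empty:
        raise ValueError("empty gene table")
    se = gene_table["se"].to_numpy(dtype=float)
    beta = gene_table["beta"].to_numpy(dtype=float)
    if not np.any(np.isfinite(se)):
        raise ValueError("all standard errors nonfinite")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    labf = 0.5 * np.log(v / (v + w)) + 0.5 * z2 * w / (v + w)
    labf -= labf.max()
    pip = np.exp(labf)
    pip /= pip.sum()
    out = gene_table.copy()
    out["pip"] = pip
    order = np.argsort(-pip, kind="mergesort")
    csum = np.cumsum(pip[order])
    k = int(np.searchsorted(csum, 0.95) + 1)
    in_cs = np.zeros(len(pip), dtype=bool)
    in_cs[order[:k]] = True
    out["in_cs95"] = in_cs
    return out


def maxcpp(finemapped: pd.DataFrame) -> pd.Series:
    """Per-variant MaxCPP: the maximum credible-set PIP across genes.

    Variants never inside a 95% credible set receive 0.
    """
    contrib = finemapped["pip"].where(finemapped["in_cs95"], 0.0)
    return contrib.groupby(finemapped["variant"]).max()


def pi1_replication(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    on: tuple[str, ...] = ("gene", "variant", "cell_type"),
) -> float:
    """Storey pi1 of replication p-values at discovery lead variants."""
    leads = discovery[discovery["is_lead"]][list(on)]
    merged = leads.merge(replication[[*on, "p"]], on=list(on), how="inner")
    if merged.empty:
        raise ValueError("no matched lead variants between datasets")
    return qvalue.pi1(merged["p"].to_numpy())


@dataclass
class BinDensityProfile:
    """Summed per-bin counts of functional elements around lead variants."""

    counts: np.ndarray
    window_bp: int
    bin_bp: int
    n_leads: int

    @property
    def n_bins(self) -> int:
        return self.counts.size


def ocr_bin_density(
    leads: pd.DataFrame,
    ocr: pd.DataFrame,
    window_bp: int = 2_000_000,
    bin_bp: int = 10_000,
) -> BinDensityProfile:
    """Count functional elements per 10-kb bin in a 2 Mb window per lead.

    ``leads`` needs 1-based ``pos`` and ``chrom``; ``ocr`` intervals are
    0-based half-open (BED semantics). An element overlapping several bins
    is counted in each; profiles are summed over lead variants.
    """
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be a multiple of bin_bp")
    n_bins = window_bp // bin_bp
    counts = np.zeros(n_bins, dtype=int)
    by_chrom = {c: g for c, g in ocr.groupby("chrom")}
    lead_rows = leads[leads["is_lead"]] if "is_lead" in leads else leads
    for _, row in lead_rows.iterrows():
        elems = by_chrom.get(row["chrom"])
        if elems is None:
            continue
        ws = int(row["pos"]) - 1 - window_bp // 2  # 0-based window start
        we = ws + window_bp
        sel = elems[(elems["end"] > max(ws, 0)) & (elems["start"] < we)]
        for s, e in zip(sel["start"], sel["end"]):
            lo = max(int((s - ws) // bin_bp), 0)
            hi = min(int((e - 1 - ws) // bin_bp), n_bins - 1)
            if hi >= lo:
                counts[lo:hi + 1] += 1
    return BinDensityProfile(counts=counts, window_bp=window_bp,
                             bin_bp=bin_bp, n_leads=len(lead_rows))
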