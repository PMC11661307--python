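"""Pairwise Bayesian colocalization over a shared variant window.

Per-variant approximate Bayes factors (Wakefield) for each trait are
combined over the single-causal-variant configurations of the five
hypotheses — no association (H0), trait 1 only (H1), trait 2 only (H2),
two distinct causal variants (H3), one shared causal variant (H4) — with
priors p1, p2, p12 per configuration, and normalized into posterior
probabilities PP0..PP4. Effects are assumed to be on standardized traits
(phenotypic variance 1), with prior effect SD W = 0.15. All sums are in
log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["ColocResult", "harmonize", "coloc_abf", "coloc_scan", "wakefield_labf"]

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
PRIOR_SD = 0.15
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: np.ndarray  # PP0..PP4
    h4_weights: pd.Series  # per-variant posterior weight under H4
    n_variants: int
    degenerate: bool = False  # fewer than 2 variants: H3 not estimable
    gene: str | None = None
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if abs(self.pp.sum() - 1.0) > 1e-8:
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def wakefield_labf(beta: np.ndarray, se: np.ndarray,
                   prior_sd: float = PRIOR_SD) -> np.ndarray:
    """Per-variant log approximate Bayes factor against beta = 0."""
    v = np.asarray(se, dtype=float) ** 2
    if (v <= 0).any():
        raise ValueError("standard errors must be positive")
    w = prior_sd**2
    z2 = (np.asarray(beta, dtype=float) / se) ** 2
    return 0.5 * np.log(v / (v + w)) + 0.5 * z2 * w / (v + w)


def harmonize(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two summary-statistic tables on position and alleles.

    Variants are matched on (chrom, pos); where REF/ALT are swapped the
    sign of b's effect is flipped; strand-ambiguous variants (A/T or C/G)
    are dropped, as are allele mismatches.
    """
    m = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if m.empty:
        raise ValueError("no overlapping variants between traits")
    ra, aa = m["ref_a"].str.upper(), m["alt_a"].str.upper()
    rb, ab = m["ref_b"].str.upper(), m["alt_b"].str.upper()
    ambiguous = pd.Series(
        [set(x) in _AMBIGUOUS for x in zip(ra, aa)], index=m.index)
    same = (ra == rb) & (aa == ab)
    flipped = (ra == ab) & (aa == rb)
    keep = (same | flipped) & ~ambiguous
    m = m[keep].copy()
    if m.empty:
        raise ValueError("no harmonizable variants between traits")
    m.loc[flipped[keep], "beta_b"] *= -1.0
    cols_a = {"chrom": m["chrom"], "pos": m["pos"], "ref": m["ref_a"],
              "alt": m["alt_a"], "beta": m["beta_a"], "se": m["se_a"]}
    cols_b = {"chrom": m["chrom"], "pos": m["pos"], "ref": m["ref_a"],
              "alt": m["alt_a"], "beta": m["beta_b"], "se": m["se_b"]}
    if "variant_a" in m:
        cols_a["variant"] = cols_b["variant"] = m["variant_a"]
    elif "variant" in m:
        cols_a["variant"] = cols_b["variant"] = m["variant"]
    return pd.DataFrame(cols_a), pd.DataFrame(cols_b)


def coloc_abf(
    a: pd.DataFrame,
    b: pd.DataFrame,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd: float = PRIOR_SD,
) -> ColocResult:
    """Colocalization posterior from two aligned summary-statistic tables.

    Hypothesis evidence:
    ``H1 = sum_v ABF_a(v)``, ``H2 = sum_v ABF_b(v)``,
    ``H3 = sum_{v != w} ABF_a(v) ABF_b(w)``,
    ``H4 = sum_v ABF_a(v) ABF_b(v)``,
    each multiplied by its configuration prior (p1, p2, p1*p2, p12) and
    normalized together with H0 (evidence 1).
    """
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("traits must share an identical, nonempty variant set")
    p1, p2, p12 = priors
    la = wakefield_labf(a["beta"].to_numpy(), a["se"].to_numpy(), prior_sd)
    lb = wakefield_labf(b["beta"].to_numpy(), b["se"].to_numpy(), prior_sd)
    lsum_a = logsumexp(la)
    lsum_b = logsumexp(lb)
    lsum_ab = logsumexp(la + lb)
    degenerate = len(a) < 2

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + lsum_a
    lh[2] = np.log(p2) + lsum_b
    cross = lsum_a + lsum_b
    if degenerate or cross <= lsum_ab:
        lh[3] = -np.inf
    else:
        lh[3] = np.log(p1) + np.log(p2) + cross + np.log1p(
            -np.exp(lsum_ab - cross))
    lh[4] = np.log(p12) + lsum_ab
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()

    h4w = np.exp(la + lb - lsum_ab)
    names = a["variant"] if "variant" in a else a["pos"].astype(str)
    return ColocResult(pp=pp, h4_weights=pd.Series(h4w, index=list(names)),
                       n_variants=len(a), degenerate=degenerate)


def coloc_scan(
    eqtls: pd.DataFrame,
    gwas: pd.DataFrame,
    genes: list[str] | None = None,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
) -> pd.DataFrame:
    """Run coloc for every (gene, cell type) against one GWAS trait.

    ``eqtls`` is a long cis table (gene, cell_type, variant, chrom, pos,
    beta, se); the GWAS table is restricted to each gene's cis variants by
    position. Returns one row per pair with PP0..PP4 and the top H4
    variant.
    """
    rows = []
    gwas_keyed = gwas.set_index(["chrom", "pos"])
    for (gene, ct), sub in eqtls.groupby(["gene", "cell_type"], sort=True):
        if genes is not None and gene not in genes:
            continue
        key = pd.MultiIndex.from_frame(sub[["chrom", "pos"]])
        present = key.isin(gwas_keyed.index)
        if not present.any():
            continue
        sub = sub[present]
        gsub = gwas_keyed.loc[key[present]].reset_index()
        a = sub.rename(columns={"beta": "beta", "se": "se"})[
            ["variant", "chrom", "pos", "beta", "se"]]
        b = gsub[["chrom", "pos", "beta", "se"]].copy()
        b.insert(0, "variant", list(a["variant"]))
        res = coloc_abf(a, b, priors=priors)
        top = res.h4_weights.idxmax()
        rows.append((gene, ct, *res.pp, res.n_variants, top,
                     float(res.h4_weights.max())))
    return pd.DataFrame(rows, columns=[
        "gene", "cell_type", "pp0", "pp1", "pp2", "pp3", "pp4",
        "n_variants", "top_h4_variant", "top_h4_weight",
    ])
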