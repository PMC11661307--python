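"""Pseudobulk construction and normalization.

Nucleus counts are summed per donor within each cell type, modelled with a
per-gene Poisson working model (log library-depth offset plus technical
covariates such as sample pool and mitochondrial fraction), and converted
to Pearson residuals which are then standardized per gene. Hidden expression
confounders are captured by principal components, with the number of
factors chosen by the count of significant eGenes it yields — mirroring the
usual latent-factor sweep in population-scale eQTL studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PseudobulkExpression",
    "FactorSweepResult",
    "aggregate",
    "normalize",
    "hidden_factor_sweep",
]


@dataclass
class PseudobulkExpression:
    """Donor x cell-type pseudobulk container.

    ``counts[ct]`` holds raw summed counts (genes x donors); after
    :func:`normalize`, ``residuals[ct]`` holds standardized Pearson
    residuals for the genes passing the expression filter. Donors without
    nuclei in a cell type are absent from that cell type's matrices.
    """

    counts: dict[str, pd.DataFrame]
    covariates: dict[str, pd.DataFrame]
    n_nuclei: dict[str, pd.Series]
    genes: pd.DataFrame
    level: str
    residuals: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(self.counts)


@dataclass
class FactorSweepResult:
    """eGene yield per candidate hidden-factor count."""

    grid: list[int]
    egene_counts: list[int]
    selected: int


def aggregate(adata: ad.AnnData, level: str = "subclass") -> PseudobulkExpression:
    """Sum nucleus counts to donor x cell-type pseudobulk.

    ``level`` selects the ``cell_class`` or ``cell_subclass`` metadata
    column. Donor covariates carried over: pool, sex (assumed constant per
    donor), mean mitochondrial fraction, mean age, total library depth and
    the number of nuclei aggregated.
    """
    if level not in {"class", "subclass"}:
        raise ValueError(f"level must be 'class' or 'subclass', got {level!r}")
    col = "cell_class" if level == "class" else "cell_subclass"
    if col not in adata.obs:
        raise ValueError(f"nucleus table lacks column {col!r}")
    x = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    labels = adata.obs[col].astype(str)

    counts, covs, n_nuclei = {}, {}, {}
    for ct in sorted(labels.unique()):
        rows = np.flatnonzero((labels == ct).to_numpy())
        sub = adata.obs.iloc[rows]
        donors = sorted(sub["donor"].unique())
        d_index = {d: i for i, d in enumerate(donors)}
        ind = sparse.csr_matrix(
            (np.ones(rows.size),
             ([d_index[d] for d in sub["donor"]], np.arange(rows.size))),
            shape=(len(donors), rows.size),
        )
        mat = np.asarray((ind @ x[rows]).todense())
        counts[ct] = pd.DataFrame(mat.T, index=adata.var_names, columns=donors)
        agg = sub.groupby("donor", observed=True).agg(
            pool=("pool", "first"),
            sex=("sex", "first"),
            age=("age", "mean"),
            mito_frac=("mito_frac", "mean"),
        ).loc[donors]
        agg["depth"] = mat.sum(axis=1)
        covs[ct] = agg
        n_nuclei[ct] = sub.groupby("donor", observed=True).size().loc[donors]

    genes = adata.var.reset_index(names="gene")
    return PseudobulkExpression(counts=counts, covariates=covs,
                                n_nuclei=n_nuclei, genes=genes, level=level)


def _poisson_pearson(y: np.ndarray, design: np.ndarray,
                     offset: np.ndarray, max_iter: int = 50,
                     tol: float = 1e-10) -> np.ndarray:
    """IRLS fit of a Poisson log-linear model; returns Pearson residuals."""
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    dev_old = np.inf
    for _ in range(max_iter):
        w = mu
        z = eta - offset + (y - mu) / mu
        wsq = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * wsq[:, None], z * wsq, rcond=None)
        eta = design @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2 * np.sum(np.where(y > 0, y * np.log(y / mu), 0) - (y - mu))
        if abs(dev - dev_old) < tol * (abs(dev) + 1):
            break
        dev_old = dev
    return (y - mu) / np.sqrt(mu)


def _build_design(cov: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for c in covariates:
        if c not in cov.columns:
            raise KeyError(f"covariate {c!r} missing from donor table")
        v = cov[c]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, drop_first=True, dtype=float)
            for name in dummies:
                cols.append(dummies[name].to_numpy())
                names.append(f"{c}[{name}]")
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
    design = np.column_stack(cols)
    # drop constant (non-intercept) and duplicate columns
    keep = [0]
    for j in range(1, design.shape[1]):
        col = design[:, j]
        if np.ptp(col) == 0:
            warnings.warn(f"dropping constant covariate column {names[j]!r}",
                          stacklevel=3)
            continue
        if any(np.allclose(col, design[:, k]) for k in keep):
            warnings.warn(f"dropping duplicate covariate column {names[j]!r}",
                          stacklevel=3)
            continue
        keep.append(j)
    return design[:, keep]


def normalize(
    pb: PseudobulkExpression,
    covariates: list[str] = ("pool", "mito_frac"),
    min_donors: int = 20,
) -> PseudobulkExpression:
    """Covariate-adjusted standardized Pearson residuals per cell type.

    Per gene: Poisson log-linear fit with log-depth offset and the given
    covariates; residual = (observed - fitted) / fitted SD, then centred
    and scaled to unit variance across donors so downstream effect sizes
    are on a standardized-expression scale. Genes nonzero in fewer than
    ``min_donors`` donors are excluded for that cell type.
    """
    covariates = list(covariates)
    for ct, mat in pb.counts.items():
        cov = pb.covariates[ct]
        depth = cov["depth"].to_numpy(dtype=float)
        if (depth <= 0).any():
            raise ValueError(f"{ct}: donor with zero total depth")
        offset = np.log(depth)
        design = _build_design(cov, covariates)
        y_all = mat.to_numpy(dtype=float)
        expressed = (y_all > 0).sum(axis=1) >= min(min_donors, mat.shape[1])
        out = {}
        for gi in np.flatnonzero(expressed):
            r = _poisson_pearson(y_all[gi], design, offset)
            sd = r.std()
            out[mat.index[gi]] = (r - r.mean()) / (sd if sd > 0 else 1.0)
        pb.residuals[ct] = pd.DataFrame.from_dict(
            out, orient="index", columns=mat.columns, dtype=float)
    return pb


def expression_pcs(residuals: pd.DataFrame, n_factors: int) -> np.ndarray:
    """Top principal components of donors (donors x n_factors)."""
    if n_factors == 0:
        return np.empty((residuals.shape[1], 0))
    x = residuals.to_numpy().T  # donors x genes
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_factors] * s[:n_factors]


def hidden_factor_sweep(
    pb: PseudobulkExpression,
    genotypes,
    grid: list[int],
    cell_type: str | None = None,
    n_pcs: int = 5,
    **map_kwargs,
) -> FactorSweepResult:
    """Choose the hidden-factor count maximizing the eGene yield.

    For each factor count ``f`` in ``grid``, the top-``f`` expression PCs
    are added to the cis-mapping covariates and the number of significant
    eGenes (BH 5% on Bonferroni-adjusted lead p-values) is recorded. Ties
    resolve to the smallest count. Deterministic given inputs.
    """
    from . import cis

    if not grid:
        raise ValueError("empty factor grid")
    cts = [cell_type] if cell_type else pb.cell_types
    counts = []
    for f in sorted(set(int(g) for g in grid)):
        total = 0
        for ct in cts:
            res = pb.residuals[ct]
            if f >= res.shape[1]:
                raise ValueError(f"{f} factors >= {res.shape[1]} donors")
            factors = expression_pcs(res, f)
            table = cis.map_cis(pb, genotypes, cell_types=[ct],
                                extra_covariates={ct: factors}, **map_kwargs)
            total += int(cis.egene_calling(table)["egene"].sum())
        counts.append(total)
    grid_sorted = sorted(set(int(g) for g in grid))
    best = int(np.argmax(counts))  # argmax takes the first = smallest on ties
    return FactorSweepResult(grid=grid_sorted, egene_counts=counts,
                             selected=grid_sorted[best])
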