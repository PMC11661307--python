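"""Readers and writers for the on-disk interchange formats.

Genotypes travel as VCF (GT field, read back through cyvcf2), counts as
MatrixMarket MTX with features/barcodes TSVs, nucleus metadata as TSV and
ground truth as JSON. All coordinates are 1-based on I/O and 0-based
half-open internally (BED stays 0-based half-open as defined).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .simulate import GenotypeMatrix, GroundTruth, SharingPattern, TransChain

__all__ = [
    "write_vcf", "read_vcf",
    "write_counts", "read_counts",
    "write_ground_truth", "read_ground_truth",
    "read_bed",
]

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCFv4.2 with GT genotypes (1-based pos)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genotypes.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.donors) + "\n")
        dos = genotypes.dosages
        for j, row in genotypes.variants.iterrows():
            gts = "\t".join(_GT_CODES[int(d)] for d in dos[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(
    path: str | Path,
    genes: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` (dosage = ALT allele count).

    ``genes`` optionally supplies the gene table (gene, chrom, tss, strand)
    that VCF itself cannot carry; cis-gene assignment of each variant is
    left empty when absent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    rows, dosage_rows = [], []
    for rec in vcf:
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = rec.gt_types.copy()
        gt[gt == 2] = 0
        gt[gt == 3] = 2
        dosage_rows.append(gt.astype(np.int8))
        rows.append({
            "variant": rec.ID or f"{rec.CHROM}:{rec.POS}",
            "chrom": rec.CHROM,
            "pos": rec.POS,
            "ref": rec.REF,
            "alt": rec.ALT[0] if rec.ALT else ".",
            "cis_gene": "",
        })
    variants = pd.DataFrame(rows)
    dosages = np.stack(dosage_rows, axis=1)
    af = dosages.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(af, 1 - af)
    if genes is None:
        genes = pd.DataFrame(columns=["gene", "chrom", "tss", "strand"])
    return GenotypeMatrix(dosages=dosages, donors=donors, variants=variants,
                          genes=genes)


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as matrix.mtx + features.tsv + barcodes.tsv + metadata.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if not sparse.issparse(x):
        x = sparse.csr_matrix(x)
    scio.mmwrite(outdir / "matrix.mtx", x.T.astype(int))  # genes x nuclei
    feats = adata.var.reset_index().rename(columns={"index": "gene"})
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False)
    adata.obs.reset_index(names="barcode").to_csv(
        outdir / "metadata.tsv", sep="\t", index=False)


def read_counts(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    x = scio.mmread(indir / "matrix.mtx").T.tocsr()
    feats = pd.read_csv(indir / "features.tsv", sep="\t").set_index("gene")
    obs = pd.read_csv(indir / "metadata.tsv", sep="\t").set_index("barcode")
    return ad.AnnData(X=x, obs=obs, var=feats)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "patterns": {
            g: {
                "label": p.label,
                "active_cell_types": sorted(p.active_cell_types),
                "effect_size": p.effect_size,
            }
            for g, p in truth.patterns.items()
        },
        "dynamic_beta": truth.dynamic_beta,
        "chains": [dataclasses.asdict(c) for c in truth.chains],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    patterns = {
        g: SharingPattern(d["label"], frozenset(d["active_cell_types"]),
                          d["effect_size"])
        for g, d in payload["patterns"].items()
    }
    chains = [TransChain(**c) for c in payload["chains"]]
    return GroundTruth(patterns=patterns,
                       dynamic_beta=payload["dynamic_beta"], chains=chains)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED (0-based half-open) into chrom/start/end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: malformed BED coordinates") from err
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: BED interval with end < start")
    return df
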