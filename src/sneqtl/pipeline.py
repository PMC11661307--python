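"""End-to-end pipeline wiring: simulate -> pseudobulk -> cis -> finemap ->
specificity -> coloc -> dynamic -> trans -> mediate -> enrich.

Stages run in dependency order on an in-memory state, each writing its
tables under the output directory with a header naming the producing
stage and the configuration hash. A manifest records per-stage row counts
and derived seeds; identical configurations produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cis, coloc, dynamic, io as sio, pseudobulk, specificity, trans
from .simulate import (
    SimConfig,
    make_ground_truth,
    simulate_genotypes,
    simulate_gwas,
    simulate_nuclei,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ["simulate", "pseudobulk", "cis", "finemap", "specificity",
          "coloc", "dynamic", "trans", "mediate", "enrich"]

_DEPS = {
    "simulate": [],
    "pseudobulk": ["simulate"],
    "cis": ["pseudobulk"],
    "finemap": ["cis"],
    "specificity": ["cis"],
    "coloc": ["cis"],
    "dynamic": ["cis"],
    "trans": ["cis"],
    "mediate": ["trans"],
    "enrich": ["dynamic", "coloc"],
}


@dataclass
class PipelineConfig:
    """All paths, thresholds and the global seed for one pipeline run.

    Every stochastic stage receives a seed derived deterministically from
    ``seed`` and the stage name.
    """

    outdir: str = "sneqtl_out"
    seed: int = 0
    level: str = "subclass"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulation scale
    n_donors: int = 150
    n_genes: int = 40
    n_variants_per_gene: int = 8
    n_cell_types: int = 3
    nuclei_per_donor_mean: float = 12.0
    dynamic_fraction: float = 0.15
    trans_chains: int = 2
    trans_a_path: float = 1.0
    trans_b_path: float = 0.9
    # thresholds
    cis_window: float = 1e6
    min_donors_expressed: int = 20
    n_min_donors: int = 30
    n_genotype_pcs: int = 5
    factor_grid: list[int] = field(default_factory=lambda: [0, 2, 4])
    egene_fdr: float = 0.05
    finemap_prior_sd: float = 0.15
    specificity_threshold: float = 0.5
    coloc_priors: tuple[float, float, float] = (1e-4, 1e-4, 1e-5)
    pp4_threshold: float = 0.5
    dynamic_fdr: float = 0.05
    dynamic_min_donors: int = 40
    dynamic_min_nuclei: int = 2
    sidak_k: float = 1e5
    trans_min_distance: float = 5e6
    mappability_min: float = 0.8
    mhc: tuple[str, int, int] = trans.DEFAULT_MHC
    ld_r2_min: float = 0.75
    gwas_effect: float = 0.4
    gwas_n: int = 50_000
    enrich_rounds: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mhc" in payload:
            payload["mhc"] = tuple(payload["mhc"])
        if "coloc_priors" in payload:
            payload["coloc_priors"] = tuple(payload["coloc_priors"])
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 100_003 + zlib.crc32(stage.encode()) % 99_991) \
            % (2**31)


def _write_table(df: pd.DataFrame, path: Path, stage: str,
                 confhash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={confhash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig,
                 stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; return the manifest.

    A stage whose dependency is not among the requested stages raises
    immediately, naming the missing dependency.
    """
    requested = stages if stages is not None else config.stages
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    enabled = [s for s in STAGES if s in requested]
    for s in enabled:
        for dep in _DEPS[s]:
            if dep not in enabled:
                raise ValueError(f"stage {s!r} requires stage {dep!r}, "
                                 "which is not enabled")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    confhash = config.config_hash()
    manifest: dict = {"config_hash": confhash, "seed": config.seed,
                      "stages": {}}
    state: dict = {}

    def record(stage: str, rows: int) -> None:
        manifest["stages"][stage] = {
            "rows": int(rows), "seed": config.stage_seed(stage)}

    if "simulate" in enabled:
        sim = SimConfig(
            n_donors=config.n_donors,
            n_genes=config.n_genes,
            n_variants_per_gene=config.n_variants_per_gene,
            n_cell_types=config.n_cell_types,
            nuclei_per_donor_mean=config.nuclei_per_donor_mean,
            dynamic_fraction=config.dynamic_fraction,
            trans_chains=config.trans_chains,
            trans_a_path=config.trans_a_path,
            trans_b_path=config.trans_b_path,
            seed=config.stage_seed("simulate"),
        )
        geno = simulate_genotypes(sim)
        truth = make_ground_truth(sim)
        adata = simulate_nuclei(sim, geno, truth)
        shared = [g for g, p in truth.patterns.items()
                  if p.label == "shared_all"]
        causal = f"{shared[0]}_v{(sim.n_variants_per_gene + 1) // 2}" \
            if shared else geno.variants["variant"].iloc[0]
        gwas = simulate_gwas(geno, causal, effect=config.gwas_effect,
                             n_gwas=config.gwas_n,
                             seed=config.stage_seed("simulate"))
        sio.write_vcf(geno, outdir / "genotypes.vcf")
        sio.write_counts(adata, outdir / "counts")
        sio.write_ground_truth(truth, outdir / "ground_truth.json")
        _write_table(gwas, outdir / "gwas.tsv", "simulate", confhash)
        state.update(geno=geno, truth=truth, adata=adata, gwas=gwas,
                     simconfig=sim)
        record("simulate", adata.n_obs)

    if "pseudobulk" in enabled:
        pb = pseudobulk.aggregate(state["adata"], level=config.level)
        pb = pseudobulk.normalize(pb,
                                  min_donors=config.min_donors_expressed)
        rows = 0
        for ct, res in pb.residuals.items():
            _write_table(res.reset_index(names="gene"),
                         outdir / f"residuals_{ct}.tsv", "pseudobulk",
                         confhash)
            rows += res.shape[0]
        state["pb"] = pb
        record("pseudobulk", rows)

    if "cis" in enabled:
        pb, geno = state["pb"], state["geno"]
        sweep = pseudobulk.hidden_factor_sweep(
            pb, geno, grid=config.factor_grid,
            n_pcs=config.n_genotype_pcs, window_bp=config.cis_window,
            n_min=config.n_min_donors)
        factors = {
            ct: pseudobulk.expression_pcs(pb.residuals[ct], sweep.selected)
            for ct in pb.residuals
        }
        table = cis.map_cis(pb, geno, window_bp=config.cis_window,
                            n_pcs=config.n_genotype_pcs,
                            n_min=config.n_min_donors,
                            extra_covariates=factors)
        egenes = cis.egene_calling(table, fdr=config.egene_fdr)
        _write_table(table, outdir / "cis_eqtl.tsv", "cis", confhash)
        _write_table(egenes, outdir / "egenes.tsv", "cis", confhash)
        state.update(cis_table=table, egenes=egenes, sweep=sweep,
                     factors=factors)
        record("cis", len(table))

    if "finemap" in enabled:
        table, egenes = state["cis_table"], state["egenes"]
        parts = []
        for _, row in egenes[egenes["egene"]].iterrows():
            sub = table[(table["gene"] == row["gene"])
                        & (table["cell_type"] == row["cell_type"])]
            fm = cis.finemap_abf(sub, prior_sd=config.finemap_prior_sd)
            parts.append(fm)
        fm_all = pd.concat(parts) if parts else pd.DataFrame(
            columns=[*table.columns, "pip", "in_cs95"])
        mcpp = (cis.maxcpp(fm_all).rename("maxcpp").reset_index()
                if len(fm_all) else
                pd.DataFrame(columns=["variant", "maxcpp"]))
        _write_table(fm_all, outdir / "finemap.tsv", "finemap", confhash)
        _write_table(mcpp, outdir / "maxcpp.tsv", "finemap", confhash)
        state["finemap"] = fm_all
        record("finemap", len(fm_all))

    if "specificity" in enabled:
        panel = specificity.EffectPanel.from_table(state["cis_table"])
        prior = specificity.fit_prior(panel)
        post = specificity.posterior(panel, prior)
        scan = specificity.specificity_scan(
            post, threshold=config.specificity_threshold)
        _write_table(scan.reset_index(), outdir / "specificity.tsv",
                     "specificity", confhash)
        state.update(posterior_panel=post, specificity=scan)
        record("specificity", len(scan))

    if "coloc" in enabled:
        res = coloc.coloc_scan(state["cis_table"], state["gwas"],
                               priors=config.coloc_priors)
        _write_table(res, outdir / "coloc.tsv", "coloc", confhash)
        state["coloc"] = res
        record("coloc", len(res))

    if "dynamic" in enabled:
        egenes = state["egenes"]
        leads = egenes[egenes["egene"]][["gene", "cell_type", "variant"]]
        dyn = dynamic.dynamic_scan(
            state["adata"], leads, state["geno"],
            level=config.level if config.level == "class" else "subclass",
            min_donors=config.dynamic_min_donors,
            min_nuclei=config.dynamic_min_nuclei,
            fdr=config.dynamic_fdr)
        _write_table(dyn, outdir / "dynamic.tsv", "dynamic", confhash)
        state["dynamic"] = dyn
        record("dynamic", len(dyn))

    if "trans" in enabled:
        egenes = state["egenes"]
        candidates = sorted(
            egenes[egenes["egene"]]["variant"].dropna().unique())
        if not candidates:
            candidates = [state["geno"].variants["variant"].iloc[0]]
        tr = trans.map_trans(
            state["pb"], state["geno"], candidates,
            min_distance=config.trans_min_distance,
            mappability_min=config.mappability_min, mhc=config.mhc,
            n_pcs=config.n_genotype_pcs, sidak_k=config.sidak_k,
            extra_covariates=state.get("factors"))
        hubs = trans.find_hubs(tr)
        _write_table(tr, outdir / "trans.tsv", "trans", confhash)
        _write_table(
            pd.DataFrame([{"variant": h.variant, "cell_type": h.cell_type,
                           "n_targets": len(h.targets),
                           "targets": ",".join(h.targets)} for h in hubs]),
            outdir / "trans_hubs.tsv", "trans", confhash)
        state.update(trans=tr, hubs=hubs)
        record("trans", len(tr))

    if "mediate" in enabled:
        med = trans.mediate(
            state["trans"], state["egenes"], state["geno"], state["pb"],
            ld_threshold=config.ld_r2_min, cis_window=config.cis_window)
        _write_table(med, outdir / "mediation.tsv", "mediate", confhash)
        state["mediation"] = med
        record("mediate", len(med))

    if "enrich" in enabled:
        dyn, col = state["dynamic"], state["coloc"]
        universe = set(dyn["gene"]) if len(dyn) else set()
        dynamic_genes = set(dyn[dyn["dynamic_egene"]]["gene"]) \
            if len(dyn) else set()
        coloc_genes = set(
            col[col["pp4"] >= config.pp4_threshold]["gene"]) & universe
        if universe:
            enr = dynamic.coloc_enrichment(
                dynamic_genes, coloc_genes, universe,
                rounds=config.enrich_rounds,
                seed=config.stage_seed("enrich"))
            enr_df = pd.DataFrame([dataclasses.asdict(enr)])
        else:
            enr_df = pd.DataFrame(
                columns=["observed", "null_mean", "null_se", "fold",
                         "rounds"])
        _write_table(enr_df, outdir / "enrichment.tsv", "enrich", confhash)
        record("enrich", len(enr_df))

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
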