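"""Cis mapping against brute-force OLS, fine-mapping algebra, pi1 and
bin-density semantics."""

import numpy as np
import pandas as pd
import pytest

from sneqtl import cis, qvalue
from sneqtl.simulate import (
    GenotypeMatrix,
    SharingPattern,
    SimConfig,
    make_ground_truth,
    simulate_genotypes,
    simulate_nuclei,
)
from sneqtl import pseudobulk


def _manual_genotypes(dosages, positions, chrom="chr1"):
    n, m = dosages.shape
    variants = pd.DataFrame({
        "variant": [f"v{j}" for j in range(m)],
        "chrom": chrom, "pos": positions,
        "ref": "A", "alt": "G", "cis_gene": "g1",
        "maf": dosages.mean(axis=0) / 2,
    })
    genes = pd.DataFrame({"gene": ["g1"], "chrom": [chrom],
                          "tss": [positions[0]], "strand": ["+"]})
    return GenotypeMatrix(dosages=dosages.astype(np.int8),
                          donors=[f"d{i}" for i in range(n)],
                          variants=variants, genes=genes)


def _pb_from_matrix(expr, donors, genes):
    """Wrap a residual matrix as a normalized PseudobulkExpression."""
    pb = pseudobulk.PseudobulkExpression(
        counts={}, covariates={}, n_nuclei={},
        genes=pd.DataFrame({"gene": genes.index, "chrom": genes["chrom"],
                            "tss": genes["tss"], "strand": "+"}),
        level="subclass")
    pb.residuals["A"] = pd.DataFrame(expr, index=genes.index,
                                     columns=donors)
    return pb


class TestMapCis:
    def test_noiseless_slope_recovered(self):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(60, 1))
        geno = _manual_genotypes(dos, [1000])
        expr = 0.5 * dos[:, 0]
        genes = pd.DataFrame({"chrom": ["chr1"], "tss": [1000]},
                             index=["g1"])
        pb = _pb_from_matrix(expr[None, :], geno.donors, genes)
        tab = cis.map_cis(pb, geno, n_pcs=0, n_min=10)
        assert tab["beta"].iloc[0] == pytest.approx(0.5, abs=1e-10)
        assert tab["p"].iloc[0] < 1e-50

    def test_matches_normal_equations_oracle(self):
        """beta-hat and SE agree with explicit (X'X)^-1 X'y linear algebra
        on small instances, covariates included."""
        rng = np.random.default_rng(3)
        for n in (8, 10):
            dos = rng.binomial(2, 0.5, size=(n, 3))
            while (dos.std(axis=0) == 0).any():
                dos = rng.binomial(2, 0.5, size=(n, 3))
            geno = _manual_genotypes(dos, [1000, 2000, 3000])
            y = rng.normal(0, 1, n)
            cov = rng.normal(0, 1, (n, 2))
            genes = pd.DataFrame({"chrom": ["chr1"], "tss": [1000]},
                                 index=["g1"])
            pb = _pb_from_matrix(y[None, :], geno.donors, genes)
            tab = cis.map_cis(pb, geno, n_pcs=0, n_min=5,
                              extra_covariates={"A": cov})
            for j in range(3):
                x = np.column_stack([np.ones(n), cov, dos[:, j]])
                xtx_inv = np.linalg.inv(x.T @ x)
                bhat = xtx_inv @ x.T @ y
                resid = y - x @ bhat
                s2 = resid @ resid / (n - x.shape[1])
                se = np.sqrt(s2 * xtx_inv[-1, -1])
                row = tab[tab["variant"] == f"v{j}"].iloc[0]
                assert row["beta"] == pytest.approx(bhat[-1], abs=1e-10)
                assert row["se"] == pytest.approx(se, abs=1e-10)

    def test_permutation_null_calibration(self):
        """With donor labels of the genotypes permuted, ~5% of the ~2,000
        tests reach p < 0.05."""
        cfg = SimConfig(n_donors=150, n_genes=100, n_variants_per_gene=20,
                        n_cell_types=1, seed=11, ld_rho=0.0,
                        trans_chains=0, dynamic_fraction=0.0,
                        nuclei_per_donor_mean=10.0)
        geno = simulate_genotypes(cfg)
        truth = make_ground_truth(cfg)
        adata = simulate_nuclei(cfg, geno, truth)
        pb = pseudobulk.normalize(pseudobulk.aggregate(adata, "subclass"))
        rng = np.random.default_rng(5)
        perm = rng.permutation(cfg.n_donors)
        shuffled = GenotypeMatrix(
            dosages=geno.dosages[perm], donors=geno.donors,
            variants=geno.variants, genes=geno.genes)
        tab = cis.map_cis(pb, shuffled, n_pcs=0, n_min=30)
        frac = (tab["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(tab))
        assert len(tab) >= 2000
        assert abs(frac - 0.05) < 2.5 * se

    def test_monomorphic_variant_skipped(self):
        dos = np.column_stack([np.ones(20, dtype=int),
                               np.tile([0, 1], 10)])
        geno = _manual_genotypes(dos, [1000, 2000])
        genes = pd.DataFrame({"chrom": ["chr1"], "tss": [1000]},
                             index=["g1"])
        y = np.random.default_rng(0).normal(size=20)
        pb = _pb_from_matrix(y[None, :], geno.donors, genes)
        tab = cis.map_cis(pb, geno, n_pcs=0, n_min=5)
        assert tab["variant"].tolist() == ["v1"]

    def test_lead_tie_breaks_by_position(self):
        dos = np.tile(np.tile([0, 1, 2], 10)[:, None], (1, 2))
        geno = _manual_genotypes(dos, [2000, 1000])
        genes = pd.DataFrame({"chrom": ["chr1"], "tss": [1500]},
                             index=["g1"])
        y = np.random.default_rng(1).normal(size=30) + dos[:, 0]
        pb = _pb_from_matrix(y[None, :], geno.donors, genes)
        tab = cis.map_cis(pb, geno, n_pcs=0, n_min=5)
        lead = tab[tab["is_lead"]]
        # identical dosages: identical p; smaller position wins
        assert lead["pos"].iloc[0] == 1000


class TestEgeneCalling:
    def test_single_null_gene(self):
        tab = pd.DataFrame({
            "gene": ["g1"], "variant": ["v1"], "chrom": ["chr1"],
            "pos": [1], "cell_type": ["A"], "beta": [0.0], "se": [1.0],
            "p": [1.0], "maf": [0.3], "n": [100], "is_lead": [True],
        })
        res = cis.egene_calling(tab)
        assert res["q"].iloc[0] == 1.0
        assert not res["egene"].iloc[0]

    def test_null_simulation_fdr(self, rng):
        """All-null genes: eGene calls are rare (BH controls the global
        error)."""
        cfg = SimConfig(n_donors=120, n_genes=80, n_variants_per_gene=5,
                        n_cell_types=2, seed=21, trans_chains=0,
                        dynamic_fraction=0.0,
                        effect_patterns=[
                            SharingPattern("null", frozenset(), 0.0)])
        geno = simulate_genotypes(cfg)
        truth = make_ground_truth(cfg)
        adata = simulate_nuclei(cfg, geno, truth)
        pb = pseudobulk.normalize(pseudobulk.aggregate(adata, "subclass"))
        tab = cis.map_cis(pb, geno, n_min=30)
        res = cis.egene_calling(tab)
        assert res["egene"].mean() <= 0.05

    def test_planted_effect_power(self):
        """beta = 0.8 at 200 donors: nearly all planted genes detected."""
        cfg = SimConfig(n_donors=200, n_genes=40, n_variants_per_gene=5,
                        n_cell_types=1, seed=22, trans_chains=0,
                        dynamic_fraction=0.0, maf_range=(0.25, 0.35),
                        effect_patterns=[
                            SharingPattern("shared_all",
                                           frozenset({"Astro"}), 0.8)])
        geno = simulate_genotypes(cfg)
        truth = make_ground_truth(cfg)
        adata = simulate_nuclei(cfg, geno, truth)
        pb = pseudobulk.normalize(pseudobulk.aggregate(adata, "subclass"))
        tab = cis.map_cis(pb, geno, n_min=30)
        res = cis.egene_calling(tab)
        assert res["egene"].mean() > 0.9


class TestFinemap:
    @staticmethod
    def _table(betas, ses):
        return pd.DataFrame({
            "variant": [f"v{i}" for i in range(len(betas))],
            "beta": betas, "se": ses,
        })

    def test_single_variant_pip_one(self):
        fm = cis.finemap_abf(self._table([0.4], [0.1]))
        assert fm["pip"].iloc[0] == 1.0
        assert fm["in_cs95"].iloc[0]

    def test_ten_identical_variants(self):
        fm = cis.finemap_abf(self._table([0.3] * 10, [0.1] * 10))
        assert np.allclose(fm["pip"], 0.1)
        assert fm["in_cs95"].sum() == 10  # 9 variants only reach 0.9

    def test_zero_z_equal_se_uniform(self):
        fm = cis.finemap_abf(self._table([0.0] * 7, [0.2] * 7))
        assert np.allclose(fm["pip"], 1 / 7)

    def test_pip_sum_and_sign_invariance(self, rng):
        betas = rng.normal(0, 0.3, 40)
        ses = rng.uniform(0.05, 0.3, 40)
        fm = cis.finemap_abf(self._table(betas, ses))
        assert fm["pip"].sum() == pytest.approx(1.0, abs=1e-12)
        flipped = cis.finemap_abf(self._table(-betas, ses))
        assert np.allclose(fm["pip"], flipped["pip"], atol=1e-12)

    def test_credible_set_shrinks_with_sharper_signal(self):
        sizes = []
        for zlead in (1.0, 3.0, 6.0):
            betas = [0.1 * zlead] + [0.05] * 9
            fm = cis.finemap_abf(self._table(betas, [0.1] * 10))
            sizes.append(int(fm["in_cs95"].sum()))
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_maxcpp_across_genes(self):
        fm = pd.concat([
            cis.finemap_abf(self._table([0.5, 0.0], [0.1, 0.1])
                            ).assign(gene="g1"),
            cis.finemap_abf(self._table([0.1, 0.1], [0.1, 0.1])
                            ).assign(gene="g2"),
        ])
        m = cis.maxcpp(fm)
        # v0 strong in g1; in g2 both variants are split 50/50
        assert m["v0"] > 0.9
        assert m["v1"] == pytest.approx(0.5, abs=0.01)


class TestPi1:
    def test_uniform_null(self, rng):
        p = rng.uniform(0, 1, 5000)
        assert qvalue.pi1(p) < 0.05

    def test_all_tiny(self):
        assert qvalue.pi1(np.full(5000, 1e-12)) == pytest.approx(1.0,
                                                                 abs=0.01)

    def test_mixture_recovery(self, rng):
        """30/70 alternative/null mixture: pi1 within 0.03 of 0.30."""
        from scipy.stats import norm

        null = rng.uniform(0, 1, 3500)
        z = rng.normal(4.0, 1.0, 1500)
        alt = 2 * norm.sf(np.abs(z))
        p = np.concatenate([null, alt])
        assert qvalue.pi1(p) == pytest.approx(0.30, abs=0.03)

    def test_few_pairs_warn(self, rng):
        with pytest.warns(UserWarning, match="uncertainty"):
            qvalue.pi1(rng.uniform(0, 1, 10))

    def test_replication_matching(self, small_cis_table):
        disc = small_cis_table
        repl = small_cis_table.copy()
        val = cis.pi1_replication(disc, repl)
        assert 0.0 <= val <= 1.0


class TestOcrBinDensity:
    def test_single_element_central_bin(self):
        leads = pd.DataFrame({"chrom": ["chr1"], "pos": [2_000_001],
                              "is_lead": [True]})
        # central bin covers [2,000,000, 2,010,000) in 0-based coords
        ocr = pd.DataFrame({"chrom": ["chr1"], "start": [2_000_000],
                            "end": [2_010_000]})
        prof = cis.ocr_bin_density(leads, ocr)
        assert prof.counts.sum() == 1
        assert prof.counts[prof.n_bins // 2] == 1

    def test_straddling_element_counted_twice(self):
        leads = pd.DataFrame({"chrom": ["chr1"], "pos": [2_000_001],
                              "is_lead": [True]})
        ocr = pd.DataFrame({"chrom": ["chr1"], "start": [2_005_000],
                            "end": [2_015_000]})
        prof = cis.ocr_bin_density(leads, ocr)
        assert prof.counts.sum() == 2
        mid = prof.n_bins // 2
        assert prof.counts[mid] == 1 and prof.counts[mid + 1] == 1

    def test_uniform_elements_flat_profile(self, rng):
        """Uniformly scattered elements around random leads: flat profile
        within Poisson fluctuation."""
        leads = pd.DataFrame({
            "chrom": "chr1",
            "pos": rng.integers(5_000_000, 50_000_000, 40),
            "is_lead": True})
        starts = rng.integers(0, 60_000_000, 30_000)
        ocr = pd.DataFrame({"chrom": "chr1", "start": starts,
                            "end": starts + 500})
        prof = cis.ocr_bin_density(leads, ocr)
        mean = prof.counts.mean()
        assert prof.counts.std() < 3 * np.sqrt(mean)

    def test_window_bin_mismatch_rejected(self):
        leads = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        ocr = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1]})
        with pytest.raises(ValueError, match="multiple"):
            cis.ocr_bin_density(leads, ocr, window_bp=15_000, bin_bp=10_000)
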