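"""Sidak/BH exactness, trans filters, hub detection and the Sobel
mediation arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sneqtl import cis, pseudobulk, trans
from sneqtl.simulate import (
    SimConfig,
    make_ground_truth,
    simulate_genotypes,
    simulate_nuclei,
)


class TestSidak:
    def test_k_one_identity(self):
        assert trans.sidak_correct(np.array([0.05, 0.5]), k=1) \
            == pytest.approx(0.05, abs=1e-15)

    def test_high_precision_value(self):
        """1 - (1 - 1e-7)^1e5 = 9.95016674585...e-3 (30-digit arbitrary-
        precision evaluation of the exact formula)."""
        got = trans.sidak_correct(np.array([1e-7]), k=1e5)
        assert got == pytest.approx(9.950166745856896e-3, abs=1e-12)

    def test_zero_and_one(self):
        assert trans.sidak_correct(np.array([0.0, 0.4])) == 0.0
        assert trans.sidak_correct(np.array([1.0])) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trans.sidak_correct(np.array([]))

    @given(st.floats(1e-12, 0.5), st.floats(1, 1e6))
    @settings(deadline=None, max_examples=100)
    def test_monotone_and_bounded(self, p, k):
        v1 = trans.sidak_correct(np.array([p]), k=k)
        v2 = trans.sidak_correct(np.array([p]), k=2 * k)
        v3 = trans.sidak_correct(np.array([p / 2]), k=k)
        assert 0.0 <= v1 <= 1.0
        assert v2 >= v1
        assert v3 <= v1


class TestStudyFdr:
    @staticmethod
    def _bh_oracle(p):
        """Textbook step-up BH with monotonicity enforcement."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * m / rank)
            q[i] = val
            prev = val
        return q

    def test_matches_reference_bh(self, rng):
        for _ in range(10):
            p = rng.uniform(0, 1, 200)
            assert np.abs(trans.study_fdr(p) - self._bh_oracle(p)).max() \
                < 1e-12

    def test_hand_computation(self):
        p = np.array([1e-9] + [0.8] * 9)
        q = trans.study_fdr(p)
        assert q[0] == pytest.approx(1e-8, rel=1e-9)  # p * m / 1

    def test_all_ones_no_discovery(self):
        q = trans.study_fdr(np.ones(50))
        assert (q == 1.0).all()


class TestLd:
    def test_identical_and_flipped(self, small_cohort):
        _, geno, _, _ = small_cohort
        v = geno.variants["variant"].iloc[0]
        assert trans.ld_r2(geno, v, v) == pytest.approx(1.0)

    def test_flipped_coding_r2_one(self):
        rng = np.random.default_rng(0)
        from sneqtl.simulate import GenotypeMatrix

        d1 = rng.binomial(2, 0.4, 100).astype(np.int8)
        dos = np.column_stack([d1, 2 - d1])
        geno = GenotypeMatrix(
            dosages=dos, donors=[f"d{i}" for i in range(100)],
            variants=pd.DataFrame({
                "variant": ["a", "b"], "chrom": "chr1",
                "pos": [1, 2], "ref": "A", "alt": "G",
                "cis_gene": "", "maf": [0.4, 0.4]}),
            genes=pd.DataFrame(columns=["gene", "chrom", "tss", "strand"]))
        assert trans.ld_r2(geno, "a", "b") == pytest.approx(1.0)

    def test_independent_variants_near_zero(self, small_cohort):
        _, geno, _, _ = small_cohort
        # variants of different genes on different chromosomes
        v1 = geno.variants["variant"].iloc[0]
        v2 = geno.variants["variant"].iloc[-1]
        assert trans.ld_r2(geno, v1, v2) < 0.1

    def test_monomorphic_rejected(self):
        from sneqtl.simulate import GenotypeMatrix

        dos = np.column_stack([np.ones(10, np.int8),
                               np.arange(10, dtype=np.int8) % 3])
        geno = GenotypeMatrix(
            dosages=dos, donors=[f"d{i}" for i in range(10)],
            variants=pd.DataFrame({
                "variant": ["a", "b"], "chrom": "chr1", "pos": [1, 2],
                "ref": "A", "alt": "G", "cis_gene": "",
                "maf": [0.5, 0.3]}),
            genes=pd.DataFrame(columns=["gene", "chrom", "tss", "strand"]))
        with pytest.raises(ValueError, match="monomorphic"):
            trans.ld_r2(geno, "a", "b")


@pytest.fixture(scope="module")
def trans_setup():
    cfg = SimConfig(n_donors=200, n_genes=24, n_variants_per_gene=5,
                    n_cell_types=2, trans_chains=2, trans_b_path=0.9,
                    seed=23, nuclei_per_donor_mean=15.0)
    geno = simulate_genotypes(cfg)
    truth = make_ground_truth(cfg)
    adata = simulate_nuclei(cfg, geno, truth)
    pb = pseudobulk.normalize(pseudobulk.aggregate(adata, "subclass"))
    table = cis.map_cis(pb, geno, n_min=30)
    eg = cis.egene_calling(table)
    cands = sorted(eg[eg["egene"]]["variant"].unique())
    return cfg, geno, truth, pb, eg, cands


class TestMapTrans:
    def test_distance_rule(self, trans_setup):
        cfg, geno, truth, pb, eg, cands = trans_setup
        res = trans.map_trans(pb, geno, cands)
        gene_info = pb.genes.set_index("gene")
        var_info = geno.variants.set_index("variant")
        for _, row in res.iterrows():
            g = gene_info.loc[row["gene"]]
            v = var_info.loc[row["variant"]]
            assert g["chrom"] != v["chrom"] or \
                abs(g["tss"] - v["pos"]) > 5e6

    def test_low_mappability_gene_excluded(self, trans_setup):
        cfg, geno, truth, pb, eg, cands = trans_setup
        excluded = pb.genes["gene"].iloc[0]
        res = trans.map_trans(pb, geno, cands,
                              mappability={excluded: 0.7})
        assert excluded not in set(res["gene"])

    def test_mhc_variant_excluded(self, trans_setup):
        cfg, geno, truth, pb, eg, cands = trans_setup
        var_info = geno.variants.set_index("variant")
        v0 = cands[0]
        mhc = (var_info.loc[v0, "chrom"],
               int(var_info.loc[v0, "pos"]) - 10,
               int(var_info.loc[v0, "pos"]) + 10)
        res = trans.map_trans(pb, geno, cands, mhc=mhc)
        assert v0 not in set(res["variant"])

    def test_planted_chain_significant(self, trans_setup):
        cfg, geno, truth, pb, eg, cands = trans_setup
        res = trans.map_trans(pb, geno, cands)
        for ch in truth.chains:
            hit = res[(res["gene"] == ch.trans_gene)
                      & (res["variant"] == ch.variant)]
            assert (hit["p"] < 1e-6).any()

    def test_unknown_candidate_rejected(self, trans_setup):
        cfg, geno, truth, pb, eg, cands = trans_setup
        with pytest.raises(KeyError, match="absent"):
            trans.map_trans(pb, geno, ["rs0_not_here"])


class TestHubs:
    @staticmethod
    def _results(pairs):
        rows = []
        for v, g, sig in pairs:
            rows.append({"gene": g, "variant": v, "chrom": "chr1",
                         "pos": 1, "cell_type": "A", "beta": 1.0,
                         "se": 0.1, "p": 1e-9, "p_sidak": 1e-4,
                         "q": 0.01, "significant": sig})
        return pd.DataFrame(rows)

    def test_three_targets_form_hub(self):
        res = self._results([("v1", f"g{i}", True) for i in range(3)])
        hubs = trans.find_hubs(res)
        assert len(hubs) == 1
        assert sorted(hubs[0].targets) == ["g0", "g1", "g2"]

    def test_two_targets_no_hub(self):
        res = self._results([("v1", "g1", True), ("v1", "g2", True)])
        assert trans.find_hubs(res) == []

    def test_planted_hub_recovered(self):
        """A variant driving 9 targets is recovered with all its
        targets."""
        res = self._results(
            [("vhub", f"g{i}", True) for i in range(9)]
            + [("v2", "g100", True), ("v3", "g200", False)])
        hubs = trans.find_hubs(res)
        assert len(hubs) == 1
        assert len(hubs[0].targets) == 9


class TestMediate:
    def test_sobel_hand_example(self):
        """a = 0.5 (SE 0.1), b = 0.4 (SE 0.1): indirect 0.20,
        Sobel SE ~ 0.0640, z ~ 3.12."""
        a, se_a, b, se_b = 0.5, 0.1, 0.4, 0.1
        indirect = a * b
        sobel = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
        assert indirect == pytest.approx(0.20)
        assert sobel == pytest.approx(0.0640, abs=5e-4)
        assert indirect / sobel == pytest.approx(3.12, abs=0.01)

    def test_full_chain_recovered(self, trans_setup):
        cfg, geno, truth, pb, eg, cands = trans_setup
        res = trans.map_trans(pb, geno, cands)
        med = trans.mediate(res, eg, geno, pb)
        assert not med.empty
        found = {(m.cis_gene, m.trans_gene)
                 for m in med[med["significant"]].itertuples()}
        planted = {(c.cis_gene, c.trans_gene) for c in truth.chains}
        assert planted & found
        for ch in truth.chains:
            rows = med[(med["cis_gene"] == ch.cis_gene)
                       & (med["trans_gene"] == ch.trans_gene)]
            assert (rows["indirect"] > 0).all()
            assert (rows["ld_r2"] >= 0.75).all()

    def test_null_b_path_not_significant(self, rng):
        """With no cis->trans path, the Sobel test stays near its nominal
        size (donor-level linear oracle)."""
        n = 300
        rejections = 0
        reps = 200
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n).astype(float)
            med = 0.5 * g + rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)  # b = 0
            (a, ), (se_a, ) = trans._ols(med, g[:, None])
            bcoef, se_b = trans._ols(y, np.column_stack([med, g]))
            z = (a * bcoef[0]) / np.sqrt(
                bcoef[0]**2 * se_a**2 + a**2 * se_b[0]**2)
            rejections += abs(z) > 1.96
        assert rejections / reps <= 0.06
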