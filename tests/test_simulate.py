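"""Synthetic cohort generator: structure, Mendelian consistency, moments."""

import numpy as np
import pandas as pd
import pytest

import pedlmm as pl
from pedlmm import SimulationConfig, gene_drop, kinship_matrix, simulate_pedigree


def test_trio_structure_counts():
    cfg = SimulationConfig(n_families=10, n_snps=2)
    ped = simulate_pedigree(cfg)
    assert len(ped) == 30
    assert len(ped.founders) == 20


def test_three_generation_has_grandparent():
    cfg = SimulationConfig(n_families=1, family_structure="three_generation", n_snps=2)
    ped = simulate_pedigree(cfg)
    assert ped.generation_depth().max() == 2


def test_nuclear_offspring_count():
    cfg = SimulationConfig(n_families=4, family_structure="nuclear", n_offspring=3, n_snps=2)
    ped = simulate_pedigree(cfg)
    assert len(ped) == 4 * 5


def test_pedigree_deterministic():
    cfg = SimulationConfig(n_families=5, n_snps=2)
    assert simulate_pedigree(cfg).ids == simulate_pedigree(cfg).ids


def test_config_yaml_roundtrip(tmp_path):
    cfg = pl.preset("dbp-like", n_families=7, seed=99)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert SimulationConfig.from_yaml(path) == cfg


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(maf_low=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(sigma_e2=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_timepoints=0)
    with pytest.raises(ValueError):
        pl.preset("unknown-preset")


class TestGeneDrop:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_families=5, n_snps=20)
        ped = simulate_pedigree(cfg)
        g1 = gene_drop(ped, cfg)
        g2 = gene_drop(ped, cfg)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)

    def test_mendelian_consistency(self):
        cfg = SimulationConfig(n_families=40, n_snps=50)
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        idx = {iid: k for k, iid in enumerate(g.sample_ids)}
        for m in ped.members:
            if m.is_founder:
                continue
            kid = g.dosage[idx[m.iid]]
            pa = g.dosage[idx[m.father]]
            ma = g.dosage[idx[m.mother]]
            # child dosage within the Mendelian envelope of its parents
            lo = (pa == 2).astype(int) + (ma == 2).astype(int)
            hi = 2 - (pa == 0).astype(int) - (ma == 0).astype(int)
            assert np.all(kid >= lo) and np.all(kid <= hi)

    def test_homozygous_parents_fix_offspring(self):
        # both parents dosage 0 at fixed-frequency SNPs -> offspring 0
        cfg = SimulationConfig(n_families=50, n_snps=30)
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        idx = {iid: k for k, iid in enumerate(g.sample_ids)}
        for m in ped.members:
            if m.is_founder:
                continue
            both0 = (g.dosage[idx[m.father]] == 0) & (g.dosage[idx[m.mother]] == 0)
            assert np.all(g.dosage[idx[m.iid]][both0] == 0)

    def test_founder_maf_matches_binomial(self):
        """Empirical founder allele frequency within 3 binomial SDs of
        the configured frequency (10,000 founders)."""
        cfg = SimulationConfig(
            n_families=5000, n_snps=3, maf_low=0.3, maf_high=0.3, causal_maf=0.3
        )
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        founders = {m.iid for m in ped.founders}
        take = [i for i, s in enumerate(g.sample_ids) if s in founders]
        n_alleles = 2 * len(take)
        freq = g.dosage[take].sum(axis=0) / n_alleles
        sd = np.sqrt(0.3 * 0.7 / n_alleles)
        assert np.all(np.abs(freq - 0.3) < 3 * sd)

    def test_causal_snp_metadata(self):
        cfg = SimulationConfig(n_families=3, n_snps=11)
        g = gene_drop(simulate_pedigree(cfg), cfg)
        j = g.snp_index("rs6442089")
        assert g.snps.loc[j, "position"] == 47956424

    def test_missingness_rate(self):
        cfg = SimulationConfig(n_families=300, n_snps=50, missing_genotype_rate=0.1)
        g = gene_drop(simulate_pedigree(cfg), cfg)
        frac = np.isnan(g.dosage).mean()
        assert frac == pytest.approx(0.1, abs=0.02)


class TestSimulatePhenotypes:
    def test_byte_identical_reproducibility(self):
        cfg = SimulationConfig(n_families=10, n_snps=5)
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        t1 = pl.simulate_phenotypes(ped, g, cfg, n_replicates=2)
        t2 = pl.simulate_phenotypes(ped, g, cfg, n_replicates=2)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a, b)
        assert not t1[0]["PHENO"].equals(t1[1]["PHENO"])  # replicates differ

    def test_pure_noise_within_individual_variance(self):
        """With no slope, trend, SNP or polygenic variance, the variance
        of an individual's phenotypes across time points is sigma_e2."""
        cfg = SimulationConfig(
            n_families=400, n_snps=2, sigma_g2=0.0, sigma_e2=9.0,
            slope_sd=0.0, time_effect=0.0, causal_effect=0.0,
            covariate_effects={},
        )
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        tbl = pl.simulate_phenotypes(ped, g, cfg, n_replicates=1)[0]
        within = tbl.groupby("IID")["PHENO"].var(ddof=1)
        # mean within-individual variance ~ sigma_e2 over 1200 individuals
        assert within.mean() == pytest.approx(9.0, rel=0.1)

    def test_causal_effect_moment(self):
        """gamma = 10, sigma_e2 = 1: mean phenotype gap between dosage-2
        and dosage-0 carriers is ~20 at baseline."""
        cfg = SimulationConfig(
            n_families=600, n_snps=3, causal_effect=10.0, sigma_e2=1.0,
            sigma_g2=1.0, slope_sd=0.0, covariate_effects={},
        )
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        tbl = pl.simulate_phenotypes(ped, g, cfg, n_replicates=1)[0]
        t1 = tbl[tbl["TIME"] == 1].set_index("IID")
        j = g.snp_index(cfg.causal_snp_id)
        dos = pd.Series(g.dosage[:, j], index=g.sample_ids)
        gap = (
            t1.loc[dos[dos == 2].index, "PHENO"].mean()
            - t1.loc[dos[dos == 0].index, "PHENO"].mean()
        )
        assert gap == pytest.approx(20.0, abs=1.5)

    def test_polygenic_covariance_recovery(self):
        """Empirical covariance of the sampled polygenic vector over
        2000 replicates on one trio matches 2*Phi*sigma_g2 entrywise."""
        cfg = SimulationConfig(
            n_families=1, n_snps=2, sigma_g2=5.0, sigma_e2=1e-8,
            slope_sd=0.0, time_effect=0.0, causal_effect=0.0,
            covariate_effects={}, n_timepoints=1, intercept=0.0,
        )
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        tables = pl.simulate_phenotypes(ped, g, cfg, n_replicates=2000)
        # with all other terms off, the phenotype at the single wave IS G
        mat = np.array(
            [t.sort_values("IID")["PHENO"].to_numpy() for t in tables]
        )
        emp = np.cov(mat.T)
        ids_sorted = sorted(ped.ids)
        kin = kinship_matrix(ped)
        order = [kin.id_index[i] for i in ids_sorted]
        expected = 2.0 * kin.phi[np.ix_(order, order)] * 5.0
        mc_tol = 4 * 5.0 / np.sqrt(2000) * 3  # generous MC band
        assert np.all(np.abs(emp - expected) < mc_tol)

    def test_ages_increase_across_waves(self):
        cfg = SimulationConfig(n_families=5, n_snps=2)
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        tbl = pl.simulate_phenotypes(ped, g, cfg, n_replicates=1)[0]
        for _, grp in tbl.groupby("IID"):
            ages = grp.sort_values("TIME")["AGE"].to_numpy()
            assert np.all(np.diff(ages) > 0)

    def test_replicate_seed_recorded(self):
        cfg = SimulationConfig(n_families=2, n_snps=2)
        ped = simulate_pedigree(cfg)
        g = gene_drop(ped, cfg)
        tables = pl.simulate_phenotypes(ped, g, cfg, n_replicates=3)
        seeds = [t.attrs["replicate_seed"] for t in tables]
        assert len(set(seeds)) == 3
        assert [t.attrs["replicate"] for t in tables] == [0, 1, 2]
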