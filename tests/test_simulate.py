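"""Generator correctness: determinism, LD structure, regression calibration."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sumtwas import (
    SimScenario,
    read_eqtl_sumstats,
    read_gwas_sumstats,
    simulate_eqtl_sumstats,
    simulate_gwas_sumstats,
    simulate_panel,
    write_scenario,
)
from sumtwas.panel import LDPanel


class TestScenarioValidation:
    def test_rho_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            SimScenario(rho=1.0)
        with pytest.raises(ValueError, match="rho"):
            SimScenario(rho=-0.1)

    def test_h2_bounds_enforced(self):
        with pytest.raises(ValueError, match="eqtl_h2"):
            SimScenario(eqtl_h2=0.0)

    def test_unknown_true_gene_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            SimScenario(n_genes=5, true_genes={"SIMG99999": 0.3})


class TestPanel:
    def test_same_seed_identical_output(self):
        sc = SimScenario(seed=11, n_genes=5, m_variants=60, n_panel=100)
        a, b = simulate_panel(sc), simulate_panel(sc)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_rho_zero_gives_near_zero_ld(self):
        n = 2_000
        sc = SimScenario(seed=12, n_genes=5, m_variants=50, n_panel=n, rho=0.0)
        panel = simulate_panel(sc)
        r2 = panel.r2(panel.variant_ids)
        off = r2[np.triu_indices_from(r2, k=1)]
        assert off.mean() < 3.0 / n

    def test_rho_09_adjacent_r2_near_081(self):
        # 5,000 diploid individuals = 10,000 haplotypes
        sc = SimScenario(seed=13, n_genes=5, m_variants=100, n_panel=5_000,
                         rho=0.9, ld_block_size=10)
        panel = simulate_panel(sc)
        r2 = panel.r2(panel.variant_ids)
        block = np.arange(100) // 10
        adjacent = [r2[i, i + 1] for i in range(99) if block[i] == block[i + 1]]
        assert np.mean(adjacent) == pytest.approx(0.81, abs=0.03)

    def test_dosage_values_and_frequencies(self):
        sc = SimScenario(seed=14, n_genes=5, m_variants=40, n_panel=300)
        panel = simulate_panel(sc)
        assert set(np.unique(panel.genotypes)) <= {0, 1, 2}
        f = panel.empirical_freq(panel.variant_ids)
        assert np.all((f >= 0) & (f <= 1))


class TestEqtlSim:
    def test_same_seed_identical_records(self):
        sc = SimScenario(seed=15, n_genes=5, m_variants=60, n_eqtl=200)
        panel = simulate_panel(sc)
        a = simulate_eqtl_sumstats(sc, panel, "placenta")
        b = simulate_eqtl_sumstats(sc, panel, "placenta")
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_marginal_beta_consistent_with_truth(self):
        """At large n the causal variant's marginal estimate sits within 3 SE of truth."""
        sc = SimScenario(seed=16, n_genes=4, m_variants=80, n_eqtl=10_000,
                         n_causal_eqtl=1, eqtl_h2=0.5, rho=0.0)
        panel = simulate_panel(sc)
        sim = simulate_eqtl_sumstats(sc, panel, "placenta")
        merged = sim.truth.eqtl.merge(sim.records, on=["gene_id", "variant_id"])
        assert len(merged) == 4
        z = (merged["beta"] - merged["beta_std"]) / merged["se"]
        assert np.all(np.abs(z) < 3)

    def test_null_genes_have_uniform_marginal_pvalues(self):
        """Genes with no causal SNPs produce ~5% of cis tests below p=0.05."""
        sc = SimScenario(seed=17, n_genes=250, m_variants=2_500, n_eqtl=500,
                         n_causal_eqtl=0, rho=0.0, cis_window=20_000)
        panel = simulate_panel(sc)
        sim = simulate_eqtl_sumstats(sc, panel, "placenta")
        p = sim.records["pvalue"].to_numpy()
        k, n = int((p < 0.05).sum()), len(p)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.05)
        assert lo <= k <= hi

    def test_unknown_tissue_rejected(self):
        sc = SimScenario(seed=18, n_genes=2, m_variants=20)
        panel = simulate_panel(sc)
        with pytest.raises(ValueError, match="tissue"):
            simulate_eqtl_sumstats(sc, panel, "kidney")


class TestGwasSim:
    def test_global_null_pvalue_rate(self):
        sc = SimScenario(seed=19, n_genes=5, m_variants=500, n_gwas=3_000,
                         rho=0.0, true_genes={})
        panel = simulate_panel(sc)
        sim = simulate_gwas_sumstats(sc, panel)
        p = sim.records["pvalue"].to_numpy()
        k, n = int((p < 0.05).sum()), len(p)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.05)
        assert lo <= k <= hi

    def test_causal_snp_marginal_beta_matches_closed_form(self):
        """Single causal SNP carrying all GReX: E[beta] = alpha*sign(b)/(sd_snp*sd_trait)."""
        alpha = 0.3
        sc = SimScenario(seed=20, n_genes=3, m_variants=60, n_gwas=20_000,
                         n_causal_eqtl=1, true_genes={"SIMG00002": alpha})
        panel = simulate_panel(sc)
        sim = simulate_gwas_sumstats(sc, panel)
        truth = sim.truth.eqtl
        causal = truth[(truth["gene_id"] == "SIMG00002") & (truth["tissue"] == "placenta")]
        vid = causal["variant_id"].iloc[0]
        sign_b = np.sign(causal["beta_raw"].iloc[0])
        g = sim.genotypes[:, panel.columns([vid])[0]].astype(float)
        sd_snp = g.std(ddof=0)
        sd_trait = np.sqrt(alpha**2 + sc.trait_noise_sd**2)
        expected = alpha * sign_b / (sd_snp * sd_trait)
        row = sim.records[sim.records["variant_id"] == vid].iloc[0]
        assert abs(row["beta"] - expected) < 3 * row["se"]

    def test_alpha_for_unknown_gene_rejected(self):
        sc = SimScenario(seed=21, n_genes=3, m_variants=30)
        panel = simulate_panel(sc)
        from sumtwas.simulate import GroundTruth
        bad = GroundTruth(eqtl=pd.DataFrame(), alpha={"NOPE": 0.5})
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_gwas_sumstats(sc, panel, truth=bad)

    def test_same_seed_identical_and_streams_differ(self):
        sc = SimScenario(seed=22, n_genes=3, m_variants=30, n_gwas=500)
        panel = simulate_panel(sc)
        a = simulate_gwas_sumstats(sc, panel)
        b = simulate_gwas_sumstats(sc, panel)
        pd.testing.assert_frame_equal(a.records, b.records)
        c = simulate_gwas_sumstats(sc, panel, stream=1)
        assert not np.array_equal(a.genotypes, c.genotypes)


class TestFileEmission:
    def test_written_files_parse_losslessly(self, tmp_path):
        sc = SimScenario(seed=23, n_genes=4, m_variants=40, n_eqtl=150,
                         n_gwas=400, true_genes={"SIMG00001": 0.2})
        paths = write_scenario(sc, tmp_path)
        panel = LDPanel.from_tsv(paths["panel"])
        np.testing.assert_array_equal(panel.genotypes, simulate_panel(sc).genotypes)
        eqtl = read_eqtl_sumstats(paths["eqtl_placenta"])
        mem = simulate_eqtl_sumstats(sc, simulate_panel(sc), "placenta").records
        assert eqtl.attrs["skipped"] == {}
        np.testing.assert_allclose(eqtl["beta"], mem["beta"], rtol=0, atol=0)
        gwas = read_gwas_sumstats(paths["gwas"])
        memg = simulate_gwas_sumstats(sc, simulate_panel(sc)).records
        assert len(gwas) == len(memg)
        np.testing.assert_allclose(gwas["zscore"], memg["zscore"], rtol=0, atol=0)

    def test_null_twas_pvalues_uniform(self, null_study):
        """Downstream gene-level p-values are uniform under the global null."""
        res = stats.kstest(null_study["pvalues"], "uniform")
        assert res.pvalue > 0.01
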