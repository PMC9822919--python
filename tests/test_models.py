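"""Model construction: FDR filter, LD clumping, variance rules."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from sumtwas import (
    BuildConfig,
    build_models,
    fdr_adjust,
    filter_gene_variance,
    ld_clump,
    snp_variance,
)
from sumtwas.models import GeneModel
from sumtwas.simulate import SimScenario, simulate_eqtl_sumstats, simulate_panel
from tests.conftest import make_panel


def bh_oracle(p):
    """Independent Benjamini-Hochberg step-up: sort, scale by m/rank, min-monotone."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFdrAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04], [0.04]),
            ([0.5, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_worked_examples(self, p, expected):
        np.testing.assert_allclose(fdr_adjust(p), expected)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [-0.1]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            fdr_adjust(bad)

    @given(hst.lists(hst.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_stepup_oracle_and_preserves_order(self, p):
        q = fdr_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), rtol=1e-12)
        assert np.all((q > 0) & (q <= 1))
        p = np.asarray(p)
        # order-preserving: a smaller p never gets a larger q
        idx = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[idx]) >= -1e-15)


class TestSnpVariance:
    @pytest.mark.parametrize(
        "eaf, beta, expected",
        [(0.5, 1.0, 0.5), (0.0, 3.0, 0.0), (1.0, -2.0, 0.0), (0.2, 0.3, 0.0288)],
    )
    def test_two_pq_beta_squared(self, eaf, beta, expected):
        assert snp_variance(eaf, beta) == pytest.approx(expected)

    def test_frequency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            snp_variance(1.2, 0.1)


def clump_oracle(candidates, r2_matrix, ids, pos, r2_threshold, window_bp):
    """Brute-force greedy clump over a precomputed full pairwise r2 matrix."""
    order = candidates.sort_values(["pvalue", "pos", "variant_id"])["variant_id"].tolist()
    loc = {v: i for i, v in enumerate(ids)}
    removed, kept = set(), []
    for v in order:
        if v in removed:
            continue
        kept.append(v)
        for u in order:
            if u == v or u in removed:
                continue
            if abs(pos[loc[u]] - pos[loc[v]]) <= window_bp and r2_matrix[loc[u], loc[v]] >= r2_threshold:
                removed.add(u)
    return kept


class TestLdClump:
    def test_single_candidate_retained(self, small_panel):
        cand = pd.DataFrame({"variant_id": ["v1"], "pos": [1000], "pvalue": [0.01]})
        assert ld_clump(cand, small_panel) == ["v1"]

    def test_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, size=500)
        noise = rng.integers(0, 3, size=500)
        b = np.where(rng.random(500) < 0.7, a, noise)  # r2 well above 0.1
        panel = make_panel(np.column_stack([a, b]), positions=[1000, 2000])
        cand = pd.DataFrame(
            {"variant_id": ["v1", "v2"], "pos": [1000, 2000], "pvalue": [1e-4, 1e-8]}
        )
        assert ld_clump(cand, panel) == ["v2"]

    def test_distant_correlated_pair_both_kept(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, size=500)
        panel = make_panel(np.column_stack([a, a]), positions=[1000, 500_000])
        cand = pd.DataFrame(
            {"variant_id": ["v1", "v2"], "pos": [1000, 500_000], "pvalue": [1e-8, 1e-4]}
        )
        assert sorted(ld_clump(cand, panel, window_bp=250_000)) == ["v1", "v2"]

    def test_missing_panel_variant_named(self, small_panel):
        cand = pd.DataFrame({"variant_id": ["nope"], "pos": [1000], "pvalue": [0.01]})
        with pytest.raises(KeyError, match="nope"):
            ld_clump(cand, small_panel)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_on_block_panel(self, seed):
        scenario = SimScenario(seed=seed, m_variants=20, n_genes=1, ld_block_size=5,
                               rho=0.8, variant_spacing=2_000, cis_window=50_000)
        panel = simulate_panel(scenario)
        rng = np.random.default_rng(seed)
        cand = pd.DataFrame(
            {
                "variant_id": panel.variant_ids,
                "pos": panel.variants["pos"],
                "pvalue": rng.uniform(1e-10, 1e-2, size=20),
            }
        )
        kept = ld_clump(cand, panel, r2_threshold=0.1, window_bp=5_000)
        r2 = panel.r2(panel.variant_ids)
        pos = panel.variants["pos"].to_numpy()
        expected = clump_oracle(cand, r2, panel.variant_ids, pos, 0.1, 5_000)
        assert kept == expected
        # no retained pair within the window is linked at or above threshold
        loc = {v: i for i, v in enumerate(panel.variant_ids)}
        for i, u in enumerate(kept):
            for v in kept[i + 1:]:
                if abs(pos[loc[u]] - pos[loc[v]]) <= 5_000:
                    assert r2[loc[u], loc[v]] < 0.1


class TestVarianceFilter:
    @pytest.mark.parametrize(
        "total, kept",
        [(0.005, False), (2.0, True), (0.5, True), (0.01, True), (2.0001, False)],
    )
    def test_strict_exclusion_outside_bounds(self, total, kept):
        variants = pd.DataFrame(
            {
                "variant_id": ["v1"],
                "effect_allele": ["A"],
                "other_allele": ["G"],
                "eaf": [0.5],
                "weight": [1.0],
                "var_explained": [total],
            }
        )
        models = {"g": GeneModel("g", "t", variants)}
        assert ("g" in filter_gene_variance(models)) is kept


def eqtl_row(gene, vid, pos, pvalue, beta=1.0, eaf=0.5):
    return dict(gene_id=gene, variant_id=vid, chrom="1", pos=pos,
                effect_allele="A", other_allele="G", eaf=eaf, beta=beta,
                se=0.1, pvalue=pvalue)


class TestBuildModels:
    def test_gene_failing_fdr_absent(self, small_panel):
        eqtls = pd.DataFrame([eqtl_row("g1", "v1", 1000, 0.2)])
        models, report = build_models(eqtls, small_panel)
        assert models == {}
        assert report.genes_after_fdr == 0

    def test_single_eqtl_gene_model_composition(self, small_panel):
        eqtls = pd.DataFrame([eqtl_row("g1", "v1", 1000, 0.01, beta=1.0, eaf=0.5)])
        models, _ = build_models(eqtls, small_panel)
        model = models["g1"]
        assert model.weights.loc["v1"] == 1.0
        assert model.total_variance == pytest.approx(0.5)

    def test_empty_input_gives_empty_models_not_error(self, small_panel):
        models, report = build_models(pd.DataFrame(), small_panel)
        assert models == {}
        assert report.genes_in == 0

    def test_total_variance_is_sum_of_parts(self, small_panel):
        eqtls = pd.DataFrame(
            [
                eqtl_row("g1", "v1", 1000, 1e-5, beta=0.5, eaf=0.3),
                eqtl_row("g1", "v5", 5000, 1e-4, beta=-0.4, eaf=0.2),
            ]
        )
        models, _ = build_models(eqtls, small_panel)
        m = models["g1"]
        assert m.total_variance == pytest.approx(m.per_snp_variance.sum())
        np.testing.assert_allclose(
            m.per_snp_variance.to_numpy(),
            snp_variance(m.variants["eaf"], m.variants["weight"]),
        )

    def test_row_order_invariance(self):
        scenario = SimScenario(seed=3, n_genes=5, m_variants=100, n_eqtl=1000)
        panel = simulate_panel(scenario)
        sim = simulate_eqtl_sumstats(scenario, panel, "placenta")
        models_a, _ = build_models(sim.records, panel)
        shuffled = sim.records.sample(frac=1.0, random_state=9).reset_index(drop=True)
        models_b, _ = build_models(shuffled, panel)
        assert sorted(models_a) == sorted(models_b)
        for g in models_a:
            pd.testing.assert_frame_equal(models_a[g].variants, models_b[g].variants)

    def test_stage_counts_never_increase(self, null_study):
        r = null_study["build_report"].to_frame()
        assert (r["n_genes"].diff().dropna() <= 0).all()
        assert (r["n_variants"].diff().dropna() <= 0).all()

    def test_ld_free_panel_clumping_removes_nothing(self):
        scenario = SimScenario(seed=4, n_genes=5, m_variants=100, n_eqtl=500,
                               rho=0.0, n_panel=2_000)
        panel = simulate_panel(scenario)
        sim = simulate_eqtl_sumstats(scenario, panel, "placenta")
        _, report = build_models(sim.records, panel)
        assert report.variants_after_clump == report.variants_after_fdr

    def test_models_tag_true_causal_variants(self):
        """Most surviving models contain a variant in strong LD with a true causal."""
        scenario = SimScenario(seed=5, n_genes=30, m_variants=300, n_eqtl=5_000,
                               eqtl_h2=0.3, n_causal_eqtl=2, cis_window=20_000)
        panel = simulate_panel(scenario)
        sim = simulate_eqtl_sumstats(scenario, panel, "placenta")
        models, _ = build_models(sim.records, panel)
        assert len(models) >= 20
        truth = sim.truth.eqtl
        n_tagged = 0
        for gene, model in models.items():
            causal = truth.loc[truth["gene_id"] == gene, "variant_id"].tolist()
            ids = list(model.variants["variant_id"]) + causal
            r2 = panel.r2(ids)
            k = len(model.variants)
            if (r2[:k, k:] >= 0.5).any():
                n_tagged += 1
        assert n_tagged / len(models) >= 0.8
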