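"""Synthetic reference panels, multi-tissue eQTL and GWAS summary statistics.

The generator produces the three inputs the pipeline consumes — a reference
genotype panel, per-tissue cis-eQTL summary statistics, and GWAS summary
statistics — from one seeded scenario, with the ground truth recorded so that
every downstream stage can be validated against known answers.

Genotypes follow a blocked-LD haplotype-copy model: within a block of
``ld_block_size`` adjacent variants sharing one allele frequency, each
haplotype allele is copied from the previous variant with probability ``rho``
and redrawn from the block frequency otherwise, giving adjacent-variant
haplotype (and dosage) correlation exactly rho and lag-k correlation rho**k;
blocks are independent. Dosages are sums of two independent haplotypes.

Expression for each gene and tissue is a sparse sum of causal dosages plus
Gaussian noise scaled so the cis-genotype fraction of expression variance is
``eqtl_h2``. The trait is a weighted sum of standardized true genetically
regulated expression (GReX) over the designated effect genes plus noise, then
standardized to unit variance (a z-score trait). Reported eQTL and GWAS
records are per-variant marginal simple-regression estimates in independent
cohorts, so summary-level methods can be checked against the individual-level
truth. The panel, eQTL and GWAS cohorts are independent draws from the same
population.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import LDPanel

# independent random streams per cohort, all derived from the scenario seed
_STREAM_POP, _STREAM_ARCH, _STREAM_PANEL, _STREAM_EQTL, _STREAM_GWAS = range(5)

# non-palindromic allele pairs cycled over variants (no strand ambiguity by default)
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class SimScenario:
    """Full description of one synthetic study; the seed determines everything.

    Sample sizes default to a 150-sample expression cohort (the scale of a
    single-tissue placental eQTL study) with a larger, desk-scale GWAS
    cohort. ``true_genes`` maps gene IDs (``gene_ids()``) to α, the trait
    effect per SD of that gene's genetically regulated expression; genes
    listed in ``exclusive_true_genes`` have causal eQTLs only in the first
    tissue, so their signal cannot be tagged by any other tissue's model.
    """

    seed: int = 0
    n_panel: int = 500
    n_eqtl: int = 150
    n_gwas: int = 20_000
    m_variants: int = 1_000
    n_genes: int = 50
    variant_spacing: int = 5_000
    cis_window: int = 50_000
    ld_block_size: int = 10
    rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_eqtl: int = 2
    eqtl_h2: float = 0.2
    tissues: tuple[str, ...] = ("placenta",)
    shared_frac: float = 0.5
    true_genes: dict[str, float] = field(default_factory=dict)
    exclusive_true_genes: tuple[str, ...] = ()
    trait_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 < self.eqtl_h2 < 1.0):
            raise ValueError("eqtl_h2 must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        known = set(self.gene_ids())
        unknown = [g for g in self.true_genes if g not in known]
        if unknown:
            raise ValueError(f"true_genes references unknown gene(s): {unknown}")
        unknown = [g for g in self.exclusive_true_genes if g not in known]
        if unknown:
            raise ValueError(f"exclusive_true_genes references unknown gene(s): {unknown}")

    def gene_ids(self) -> list[str]:
        return [f"SIMG{i + 1:05d}" for i in range(self.n_genes)]

    def gene_tss(self) -> np.ndarray:
        """Gene anchor positions, evenly spread across the simulated segment."""
        span = self.m_variants * self.variant_spacing
        return (np.arange(self.n_genes) + 0.5) * span / self.n_genes

    def _rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, stream, *extra])
        )


# ---------------------------------------------------------------------------
# Population and genotypes
# ---------------------------------------------------------------------------

def _population(scenario: SimScenario) -> pd.DataFrame:
    """Per-variant metadata shared by every cohort: position, block, frequency, alleles."""
    rng = scenario._rng(_STREAM_POP)
    m = scenario.m_variants
    block = np.arange(m) // scenario.ld_block_size
    n_blocks = int(block.max()) + 1
    lo, hi = scenario.maf_range
    block_freq = rng.uniform(lo, hi, size=n_blocks)
    pairs = [_ALLELE_PAIRS[int(i)] for i in rng.integers(0, len(_ALLELE_PAIRS), size=m)]
    return pd.DataFrame(
        {
            "variant_id": [f"var{i + 1:06d}" for i in range(m)],
            "chrom": "1",
            "pos": (np.arange(m) + 1) * scenario.variant_spacing,
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "freq": block_freq[block],
            "block": block,
        }
    )


def _draw_haplotypes(
    freq: np.ndarray, block: np.ndarray, rho: float, n_hap: int, rng
) -> np.ndarray:
    """n_hap x m binary haplotypes under the within-block copy model."""
    m = len(freq)
    h = np.empty((n_hap, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random(n_hap) < freq[j]
        if j > 0 and block[j] == block[j - 1]:
            copy = rng.random(n_hap) < rho
            h[:, j] = np.where(copy, h[:, j - 1], fresh)
        else:
            h[:, j] = fresh
    return h


def _draw_genotypes(scenario: SimScenario, pop: pd.DataFrame, n: int, rng) -> np.ndarray:
    freq = pop["freq"].to_numpy()
    block = pop["block"].to_numpy()
    h1 = _draw_haplotypes(freq, block, scenario.rho, n, rng)
    h2 = _draw_haplotypes(freq, block, scenario.rho, n, rng)
    return (h1 + h2).astype(np.int8)


def simulate_panel(scenario: SimScenario) -> LDPanel:
    """Reference panel of ``n_panel`` individuals from the scenario population."""
    pop = _population(scenario)
    geno = _draw_genotypes(scenario, pop, scenario.n_panel, scenario._rng(_STREAM_PANEL))
    return LDPanel(variants=pop.drop(columns="block"), genotypes=geno)


# ---------------------------------------------------------------------------
# Causal architecture
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True causal structure: per gene x tissue causal sets and effects.

    ``eqtl`` has one row per gene x tissue x causal variant (columns gene_id,
    tissue, variant_id, beta_raw, beta_std where beta_std is on the
    standardized-expression scale once a cohort is drawn); ``alpha`` maps
    gene -> trait effect per SD of GReX; ``gwas_marginal`` (filled by the
    GWAS generator) is the per-variant true marginal trait effect.
    """

    eqtl: pd.DataFrame
    alpha: dict[str, float]
    gwas_marginal: pd.DataFrame | None = None


def cis_variants(scenario: SimScenario, pop: pd.DataFrame, gene_index: int) -> np.ndarray:
    tss = scenario.gene_tss()[gene_index]
    pos = pop["pos"].to_numpy()
    return np.where(np.abs(pos - tss) <= scenario.cis_window)[0]


def _architecture(scenario: SimScenario, pop: pd.DataFrame) -> pd.DataFrame:
    """Choose causal variants and raw effect sizes for every gene x tissue.

    A per-gene shared causal subset (fraction ``shared_frac`` of
    ``n_causal_eqtl``, with shared raw effects) is common to all tissues;
    the remainder is tissue-specific. Genes in ``exclusive_true_genes`` are
    genetically regulated in the first tissue only.
    """
    rng = scenario._rng(_STREAM_ARCH)
    gene_ids = scenario.gene_ids()
    focal = scenario.tissues[0]
    rows = []
    for gi, gene in enumerate(gene_ids):
        cis = cis_variants(scenario, pop, gi)
        if cis.size == 0:
            raise ValueError(f"gene {gene} has zero cis variants")
        k = min(scenario.n_causal_eqtl, cis.size)
        n_shared = int(round(scenario.shared_frac * k))
        shared = rng.choice(cis, size=n_shared, replace=False)
        shared_b = rng.normal(0.0, 1.0, size=n_shared)
        exclusive = gene in scenario.exclusive_true_genes
        for tissue in scenario.tissues:
            if exclusive and tissue != focal:
                continue  # not genetically regulated outside the focal tissue
            remaining = np.setdiff1d(cis, shared)
            n_spec = k - n_shared
            spec = rng.choice(remaining, size=min(n_spec, remaining.size), replace=False)
            spec_b = rng.normal(0.0, 1.0, size=spec.size)
            for idx, b in zip(
                np.concatenate([shared, spec]), np.concatenate([shared_b, spec_b])
            ):
                rows.append(
                    {
                        "gene_id": gene,
                        "tissue": tissue,
                        "variant_id": pop["variant_id"].iloc[int(idx)],
                        "variant_index": int(idx),
                        "beta_raw": float(b),
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "variant_id", "variant_index", "beta_raw"]
    )


# ---------------------------------------------------------------------------
# Marginal regression (shared by both summary-statistic generators)
# ---------------------------------------------------------------------------

def marginal_regression(G: np.ndarray, y: np.ndarray):
    """Per-column simple linear regression of y on dosage.

    Returns (beta, se, pvalue) arrays using the standard one-predictor OLS
    formulas with a t-distributed test statistic on n-2 degrees of freedom.
    Monomorphic columns get beta 0, infinite SE and p 1.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    gm = G.mean(axis=0)
    gc = G - gm
    sxx = (gc**2).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    mono = sxx == 0
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono | (se == 0), np.inf, se)
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    pvalue = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pvalue = np.clip(pvalue, 5e-324, 1.0)
    return beta, se, pvalue


# ---------------------------------------------------------------------------
# eQTL summary statistics
# ---------------------------------------------------------------------------

@dataclass
class EqtlSim:
    """One tissue's simulated eQTL study: records, truth, and raw cohort data."""

    records: pd.DataFrame
    truth: GroundTruth
    genotypes: np.ndarray
    expression: pd.DataFrame  # standardized expression, one column per gene


def simulate_eqtl_sumstats(
    scenario: SimScenario, panel: LDPanel, tissue: str
) -> EqtlSim:
    """Marginal cis-eQTL summary statistics for one tissue, fresh cohort.

    Expression is standardized to unit SD before regression, so betas are in
    SDs of expression per effect allele; the recorded true betas
    (``beta_std``) are rescaled the same way.
    """
    if tissue not in scenario.tissues:
        raise ValueError(f"tissue {tissue!r} not in scenario.tissues")
    pop = _population(scenario)
    arch = _architecture(scenario, pop)
    t_index = scenario.tissues.index(tissue)
    rng = scenario._rng(_STREAM_EQTL, t_index)
    G = _draw_genotypes(scenario, pop, scenario.n_eqtl, rng).astype(float)

    rows = []
    truth_rows = []
    expr = {}
    for gi, gene in enumerate(scenario.gene_ids()):
        cis = cis_variants(scenario, pop, gi)
        if cis.size == 0:
            raise ValueError(f"gene {gene} has zero cis variants")
        causal = arch[(arch["gene_id"] == gene) & (arch["tissue"] == tissue)]
        if len(causal):
            gv = G[:, causal["variant_index"].to_numpy()] @ causal["beta_raw"].to_numpy()
            var_g = gv.var()
            if var_g > 0:
                noise_sd = np.sqrt(var_g * (1 - scenario.eqtl_h2) / scenario.eqtl_h2)
            else:
                noise_sd = 1.0
            y = gv + rng.normal(0.0, noise_sd, size=scenario.n_eqtl)
        else:
            y = rng.normal(0.0, 1.0, size=scenario.n_eqtl)
        sd_y = y.std(ddof=0)
        y = (y - y.mean()) / sd_y
        expr[gene] = y

        beta, se, pvalue = marginal_regression(G[:, cis], y)
        eaf = G[:, cis].mean(axis=0) / 2.0
        ok = np.isfinite(se)
        meta = pop.iloc[cis]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene,
                    "variant_id": meta["variant_id"].to_numpy()[ok],
                    "chrom": meta["chrom"].to_numpy()[ok],
                    "pos": meta["pos"].to_numpy()[ok],
                    "effect_allele": meta["effect_allele"].to_numpy()[ok],
                    "other_allele": meta["other_allele"].to_numpy()[ok],
                    "eaf": eaf[ok],
                    "beta": beta[ok],
                    "se": se[ok],
                    "pvalue": pvalue[ok],
                }
            )
        )
        for _, r in causal.iterrows():
            truth_rows.append(
                {
                    "gene_id": gene,
                    "tissue": tissue,
                    "variant_id": r["variant_id"],
                    "beta_raw": r["beta_raw"],
                    "beta_std": r["beta_raw"] / sd_y,
                }
            )

    records = pd.concat(rows, ignore_index=True)
    records["zscore"] = records["beta"] / records["se"]
    truth = GroundTruth(
        eqtl=pd.DataFrame(
            truth_rows, columns=["gene_id", "tissue", "variant_id", "beta_raw", "beta_std"]
        ),
        alpha=dict(scenario.true_genes),
    )
    return EqtlSim(
        records=records,
        truth=truth,
        genotypes=G.astype(np.int8),
        expression=pd.DataFrame(expr),
    )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class GwasSim:
    """Simulated GWAS: per-variant records, truth, and the raw cohort."""

    records: pd.DataFrame
    truth: GroundTruth
    genotypes: np.ndarray
    trait: np.ndarray
    grex: pd.DataFrame  # standardized true GReX per effect gene


def simulate_gwas_sumstats(
    scenario: SimScenario,
    panel: LDPanel,
    truth: GroundTruth | None = None,
    stream: int = 0,
) -> GwasSim:
    """GWAS summary statistics for a trait mediated by true GReX.

    The trait is Σ_g α_g · standardized GReX_g + N(0, trait_noise_sd²),
    standardized to unit variance (a z-score trait). GReX uses the first
    tissue's causal architecture. Per-variant marginal regressions over all
    panel variants give beta/se/z/p; the truth table records each variant's
    true marginal effect (the population-LD projection of the genetic trait
    component, computed in-cohort). ``stream`` selects an independent cohort
    draw, e.g. a second phenotype measured in a different consortium.
    """
    pop = _population(scenario)
    if truth is not None:
        alpha = truth.alpha
    else:
        alpha = dict(scenario.true_genes)
    unknown = [g for g in alpha if g not in set(scenario.gene_ids())]
    if unknown:
        raise ValueError(f"alpha references unknown gene(s): {unknown}")
    arch = _architecture(scenario, pop)
    focal = scenario.tissues[0]
    rng = scenario._rng(_STREAM_GWAS, stream)
    G = _draw_genotypes(scenario, pop, scenario.n_gwas, rng).astype(float)

    genetic = np.zeros(scenario.n_gwas)
    grex = {}
    for gene, a in alpha.items():
        causal = arch[(arch["gene_id"] == gene) & (arch["tissue"] == focal)]
        if not len(causal):
            continue
        gv = G[:, causal["variant_index"].to_numpy()] @ causal["beta_raw"].to_numpy()
        sd = gv.std(ddof=0)
        gv_std = (gv - gv.mean()) / sd if sd > 0 else gv * 0.0
        grex[gene] = gv_std
        genetic = genetic + a * gv_std
    y = genetic + rng.normal(0.0, scenario.trait_noise_sd, size=scenario.n_gwas)
    y = (y - y.mean()) / y.std(ddof=0)

    beta, se, pvalue = marginal_regression(G, y)
    eaf = G.mean(axis=0) / 2.0
    records = pop.drop(columns="block").copy()
    records["eaf"] = eaf
    records["beta"] = beta
    records["se"] = se
    records["pvalue"] = pvalue
    records["n"] = scenario.n_gwas
    records["zscore"] = np.where(np.isfinite(se), beta / se, 0.0)
    records = records[np.isfinite(records["se"])].reset_index(drop=True)

    # true marginal effect of each variant on the genetic trait component
    gc = G - G.mean(axis=0)
    sxx = (gc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        true_marginal = (gc.T @ (genetic - genetic.mean())) / sxx
    true_marginal = np.where(sxx > 0, true_marginal, 0.0)
    gwas_marginal = pd.DataFrame(
        {"variant_id": pop["variant_id"], "true_beta": true_marginal}
    )
    out_truth = GroundTruth(
        eqtl=truth.eqtl if truth is not None else arch.rename(
            columns={"beta_raw": "beta_raw"}
        )[["gene_id", "tissue", "variant_id", "beta_raw"]],
        alpha=dict(alpha),
        gwas_marginal=gwas_marginal,
    )
    return GwasSim(
        records=records,
        truth=out_truth,
        genotypes=G.astype(np.int8),
        trait=y,
        grex=pd.DataFrame(grex),
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_scenario(scenario: SimScenario, out_dir) -> dict[str, str]:
    """Simulate the full scenario and write panel/eQTL/GWAS/truth TSVs.

    Returns a name -> path mapping for the files written.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    panel = simulate_panel(scenario)
    panel_path = os.path.join(out_dir, "panel.tsv")
    panel.to_tsv(panel_path)
    paths["panel"] = panel_path

    truth_frames = []
    for tissue in scenario.tissues:
        sim = simulate_eqtl_sumstats(scenario, panel, tissue)
        p = os.path.join(out_dir, f"eqtl_{tissue}.tsv")
        sim.records.drop(columns="zscore").to_csv(p, sep="\t", index=False, float_format="%.17g")
        paths[f"eqtl_{tissue}"] = p
        truth_frames.append(sim.truth.eqtl)

    gwas = simulate_gwas_sumstats(scenario, panel)
    p = os.path.join(out_dir, "gwas.tsv")
    gwas.records.to_csv(p, sep="\t", index=False, float_format="%.17g")
    paths["gwas"] = p

    truth = pd.concat(truth_frames, ignore_index=True)
    truth["alpha"] = truth["gene_id"].map(scenario.true_genes).fillna(0.0)
    p = os.path.join(out_dir, "truth_eqtl.tsv")
    truth.to_csv(p, sep="\t", index=False, float_format="%.17g")
    paths["truth_eqtl"] = p
    p = os.path.join(out_dir, "truth_gwas.tsv")
    gwas.truth.gwas_marginal.to_csv(p, sep="\t", index=False, float_format="%.17g")
    paths["truth_gwas"] = p
    return paths
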