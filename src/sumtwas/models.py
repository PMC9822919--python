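"""Build gene expression prediction models from cis-eQTL summary statistics.

The builder turns each gene's marginal eQTL records into a sparse set of
prediction weights in four stages:

1. within-gene Benjamini-Hochberg FDR adjustment, keeping records with
   adjusted p (q) below a threshold (default 0.1);
2. greedy LD clumping of the survivors against a reference panel
   (default r² >= 0.1 within a ±250 kb window discards the weaker variant);
3. each retained variant is weighted by its eQTL beta, and its share of
   expression variance computed as 2·p·q·β² under Hardy-Weinberg equilibrium;
4. genes whose summed variance explained falls outside [lower, upper]
   (default [0.01, 2]) are excluded — the bounds themselves are retained
   because exclusion is strict.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .panel import LDPanel


@dataclass
class BuildConfig:
    fdr_threshold: float = 0.1
    r2_threshold: float = 0.1
    window_bp: int = 250_000
    var_bounds: tuple[float, float] = (0.01, 2.0)
    fdr_scope: str = "gene"  # "gene" (default) or "global"


@dataclass
class GeneModel:
    """Prediction weights for one gene in one tissue.

    ``variants`` has one row per retained variant with columns ``variant_id``,
    ``effect_allele``, ``other_allele``, ``eaf``, ``weight`` (expression SD per
    effect allele, the retained eQTL beta) and ``var_explained`` (2pqβ²).
    """

    gene_id: str
    tissue: str
    variants: pd.DataFrame

    @property
    def weights(self) -> pd.Series:
        return self.variants.set_index("variant_id")["weight"]

    @property
    def per_snp_variance(self) -> pd.Series:
        return self.variants.set_index("variant_id")["var_explained"]

    @property
    def total_variance(self) -> float:
        return float(self.variants["var_explained"].sum())

    @property
    def n_snps(self) -> int:
        return len(self.variants)


@dataclass
class BuildReport:
    """Gene/variant counts surviving each stage of the model build."""

    genes_in: int = 0
    variants_in: int = 0
    genes_after_fdr: int = 0
    variants_after_fdr: int = 0
    genes_after_clump: int = 0
    variants_after_clump: int = 0
    genes_final: int = 0
    variants_final: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.genes_in, self.variants_in),
            ("fdr_filter", self.genes_after_fdr, self.variants_after_fdr),
            ("ld_clump", self.genes_after_clump, self.variants_after_clump),
            ("variance_filter", self.genes_final, self.variants_final),
        ]
        return pd.DataFrame(rows, columns=["stage", "n_genes", "n_variants"])


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def snp_variance(eaf, beta):
    """Expression variance explained by a biallelic variant: 2·p·q·β²."""
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf < 0) | (eaf > 1)):
        raise ValueError("eaf must lie in [0, 1]")
    beta = np.asarray(beta, dtype=float)
    return 2.0 * eaf * (1.0 - eaf) * beta**2


def ld_clump(
    candidates: pd.DataFrame,
    panel: LDPanel,
    r2_threshold: float = 0.1,
    window_bp: int = 250_000,
) -> list[str]:
    """Greedy LD clumping; returns retained variant_ids.

    Repeatedly keep the remaining candidate with the smallest p-value (ties
    broken by position then variant_id, for determinism) and discard every
    other remaining candidate within ±window_bp whose squared dosage
    correlation with it (in the panel) is >= r2_threshold.
    """
    required = {"variant_id", "pos", "pvalue"}
    if not required.issubset(candidates.columns):
        raise ValueError(f"candidates need columns {sorted(required)}")
    missing = [v for v in candidates["variant_id"] if v not in panel]
    if missing:
        raise KeyError(f"candidate variant {missing[0]!r} not in panel")
    cand = candidates.sort_values(
        ["pvalue", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    ids = cand["variant_id"].to_numpy()
    pos = cand["pos"].to_numpy()
    x = panel.dosages(ids)
    xc = x - x.mean(axis=0)
    norm = np.sqrt((xc**2).sum(axis=0))
    alive = np.ones(len(cand), dtype=bool)
    retained: list[str] = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        retained.append(ids[i])
        alive[i] = False
        near = alive & (np.abs(pos - pos[i]) <= window_bp)
        if near.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (xc[:, near].T @ xc[:, i]) / (norm[near] * norm[i])
            r2 = np.nan_to_num(r, nan=0.0) ** 2
            kill = np.where(near)[0][r2 >= r2_threshold]
            alive[kill] = False
    return retained


def filter_gene_variance(
    models: dict[str, GeneModel],
    lower: float = 0.01,
    upper: float = 2.0,
) -> dict[str, GeneModel]:
    """Keep genes with lower <= total variance explained <= upper (strict exclusion)."""
    return {g: m for g, m in models.items() if lower <= m.total_variance <= upper}


def build_models(
    eqtls: pd.DataFrame,
    panel: LDPanel,
    config: BuildConfig | None = None,
    tissue: str = "",
) -> tuple[dict[str, GeneModel], BuildReport]:
    """Run the four-stage model build over a harmonized eQTL table.

    ``eqtls`` needs columns gene_id, variant_id, effect_allele, other_allele,
    eaf, beta, se, pvalue, pos. Returns the surviving models keyed by gene_id
    plus the per-stage count report. Empty input yields an empty model set.
    """
    cfg = config or BuildConfig()
    report = BuildReport()
    if len(eqtls) == 0:
        return {}, report
    eqtls = eqtls.copy()
    report.genes_in = eqtls["gene_id"].nunique()
    report.variants_in = len(eqtls)

    if cfg.fdr_scope == "global":
        eqtls["fdr_q"] = fdr_adjust(eqtls["pvalue"].to_numpy())
    elif cfg.fdr_scope == "gene":
        eqtls["fdr_q"] = (
            eqtls.groupby("gene_id")["pvalue"].transform(lambda p: fdr_adjust(p.to_numpy()))
        )
    else:
        raise ValueError(f"unknown fdr_scope {cfg.fdr_scope!r}")
    surv = eqtls[eqtls["fdr_q"] < cfg.fdr_threshold]
    report.genes_after_fdr = surv["gene_id"].nunique()
    report.variants_after_fdr = len(surv)

    models: dict[str, GeneModel] = {}
    n_clumped = 0
    for gene_id, grp in surv.groupby("gene_id", sort=True):
        keep = ld_clump(grp, panel, cfg.r2_threshold, cfg.window_bp)
        n_clumped += len(keep)
        sel = grp.set_index("variant_id").loc[keep].reset_index()
        variants = pd.DataFrame(
            {
                "variant_id": sel["variant_id"],
                "effect_allele": sel["effect_allele"],
                "other_allele": sel["other_allele"],
                "eaf": sel["eaf"].astype(float),
                "weight": sel["beta"].astype(float),
                "var_explained": snp_variance(sel["eaf"], sel["beta"]),
                "pos": sel["pos"].astype(int),
            }
        ).sort_values("pos", kind="mergesort").reset_index(drop=True)
        models[str(gene_id)] = GeneModel(gene_id=str(gene_id), tissue=tissue, variants=variants)
    report.genes_after_clump = len(models)
    report.variants_after_clump = n_clumped

    lower, upper = cfg.var_bounds
    models = filter_gene_variance(models, lower, upper)
    report.genes_final = len(models)
    report.variants_final = sum(m.n_snps for m in models.values())
    return models, report


def model_covariances(
    models: dict[str, GeneModel], panel: LDPanel
) -> dict[str, pd.DataFrame]:
    """Per-gene pairwise dosage covariances of the model variants, from the panel."""
    out: dict[str, pd.DataFrame] = {}
    for gene_id, model in models.items():
        ids = list(model.variants["variant_id"])
        cov = panel.covariance(ids)
        rows = []
        for i, vi in enumerate(ids):
            for j in range(i, len(ids)):
                rows.append(
                    {
                        "variant_id_1": vi,
                        "variant_id_2": ids[j],
                        "covariance": cov[i, j],
                    }
                )
        out[gene_id] = pd.DataFrame(rows, columns=["variant_id_1", "variant_id_2", "covariance"])
    return out


def covariance_matrix(cov_df: pd.DataFrame, variant_ids: list[str]) -> np.ndarray | None:
    """Assemble a dense symmetric covariance matrix from long-format pairs.

    Returns None when any required pair (including diagonals) is absent.
    """
    idx = {v: i for i, v in enumerate(variant_ids)}
    k = len(variant_ids)
    mat = np.full((k, k), np.nan)
    for _, r in cov_df.iterrows():
        v1, v2 = r["variant_id_1"], r["variant_id_2"]
        if v1 in idx and v2 in idx:
            mat[idx[v1], idx[v2]] = r["covariance"]
            mat[idx[v2], idx[v1]] = r["covariance"]
    if np.isnan(np.diag(mat)).any():
        return None
    # off-diagonal pairs missing from the file are treated as unlinked
    mat = np.nan_to_num(mat, nan=0.0)
    return mat
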