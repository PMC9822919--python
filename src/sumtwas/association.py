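"""Summary-statistic gene-trait association (S-PrediXcan-style).

For a gene with prediction weights w over variants l, GWAS per-variant
z-scores z_l and betas β_l, reference dosage standard deviations σ_l and
covariance Γ, the association statistic is

    Z_g = Σ_l w_l σ_l z_l / σ_g,       σ_g² = wᵀ Γ w,

the effect per SD of predicted expression is

    γ̂_g = Σ_l w_l σ_l² β_l / σ_g,      se_g = |γ̂_g / Z_g|,

(Σ_l w_l σ_l² β_l is cov(trait, weighted dosage score), so dividing by σ_g
rather than σ_g² expresses the slope per SD of the score — the scale on
which a gene's effect is comparable across genes and tissues)

and p = 2·Φ(−|Z_g|). σ_g² is the variance of the weighted dosage score in
the reference sample; genes whose score is numerically constant are skipped
as degenerate rather than divided by zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Harmonized, harmonize
from .models import GeneModel, covariance_matrix
from .panel import LDPanel

RESULT_COLUMNS = [
    "gene_id",
    "tissue",
    "zscore",
    "effect",
    "se",
    "pvalue",
    "sigma_g2",
    "n_snps_model",
    "n_snps_used",
]

SIGMA_FLOOR = 1e-12


@dataclass
class TissueResultSet:
    """All gene-level results for one tissue, plus the genes skipped and why."""

    tissue: str
    results: pd.DataFrame
    skipped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "reason"])
    )

    @property
    def n_tests(self) -> int:
        return len(self.results)


def predicted_expression_variance(weights: np.ndarray, covariance: np.ndarray) -> float:
    """Variance of the weighted dosage score, wᵀΓw."""
    w = np.asarray(weights, dtype=float)
    g = np.atleast_2d(np.asarray(covariance, dtype=float))
    return float(w @ g @ w)


def twas_zscore(
    weights: np.ndarray, gwas_z: np.ndarray, snp_sd: np.ndarray, sigma_g: float
) -> float:
    """Gene-level association z-score from per-variant GWAS z-scores."""
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * np.asarray(snp_sd, float) * np.asarray(gwas_z, float)) / sigma_g)


def twas_effect(
    weights: np.ndarray, gwas_beta: np.ndarray, snp_var: np.ndarray, sigma_g2: float
) -> float:
    """Gene-level effect in trait units per SD of predicted expression.

    The numerator Σ w_l σ_l² β_l equals the covariance between the trait and
    the weighted dosage score, so dividing by σ_g (not σ_g²) gives the
    regression slope per standard deviation of predicted expression. It is
    invariant to rescaling all weights by a positive constant.
    """
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    w = np.asarray(weights, dtype=float)
    cov_ys = float(np.sum(w * np.asarray(snp_var, float) * np.asarray(gwas_beta, float)))
    return cov_ys / np.sqrt(sigma_g2)


def _gene_association(
    model: GeneModel,
    gwas_idx: pd.DataFrame,
    panel: LDPanel | None,
    cov_df: pd.DataFrame | None,
    tissue: str,
    sigma_floor: float,
):
    """Compute one TwasResult row, or (None, reason) when the gene is untestable."""
    used = [v for v in model.variants["variant_id"] if v in gwas_idx.index]
    if not used:
        return None, "no_gwas_overlap"

    gamma = None
    if cov_df is not None:
        gamma = covariance_matrix(cov_df, used)
    if gamma is None:
        if panel is None:
            return None, "no_covariance"
        try:
            gamma = panel.covariance(used)
        except KeyError:
            return None, "missing_from_panel"

    w = model.weights.loc[used].to_numpy()
    snp_var = np.diag(np.atleast_2d(gamma)).copy()
    sigma_g2 = predicted_expression_variance(w, gamma)
    if sigma_g2 <= sigma_floor:
        return None, "degenerate"

    rows = gwas_idx.loc[used]
    z_g = twas_zscore(w, rows["zscore"].to_numpy(), np.sqrt(snp_var), np.sqrt(sigma_g2))
    effect = twas_effect(w, rows["beta"].to_numpy(), snp_var, sigma_g2)
    se = abs(effect / z_g) if z_g != 0 else np.nan
    pvalue = 2.0 * stats.norm.sf(abs(z_g))
    return (
        {
            "gene_id": model.gene_id,
            "tissue": tissue,
            "zscore": z_g,
            "effect": effect,
            "se": se,
            "pvalue": pvalue,
            "sigma_g2": sigma_g2,
            "n_snps_model": model.n_snps,
            "n_snps_used": len(used),
        },
        None,
    )


def run_association(
    gwas: pd.DataFrame,
    models: dict[str, GeneModel],
    panel: LDPanel | None = None,
    covariances: dict[str, pd.DataFrame] | None = None,
    tissue: str = "",
    sigma_floor: float = SIGMA_FLOOR,
    drop_ambiguous: bool = True,
    preharmonized: bool = False,
) -> TissueResultSet:
    """Associate every gene model with the trait; deterministic given inputs.

    The GWAS is harmonized to the model alleles once (set ``preharmonized``
    when the caller already did so). Γ is taken from ``covariances`` per gene
    when available, else computed from ``panel``; genes with no usable
    variants or a degenerate predicted-expression variance go to the skip
    report instead of the results.
    """
    if models:
        all_snps = pd.concat([m.variants for m in models.values()], ignore_index=True)
    else:
        all_snps = pd.DataFrame(columns=["variant_id", "effect_allele", "other_allele"])
    if preharmonized or not len(all_snps):
        harm = Harmonized(gwas=gwas, panel=panel, counts={})
    else:
        harm = harmonize(gwas, all_snps, panel=panel, drop_ambiguous=drop_ambiguous)
    gwas_idx = harm.gwas.set_index("variant_id") if len(harm.gwas) else pd.DataFrame(
        columns=["zscore", "beta"]
    )

    rows, skipped = [], []
    for gene_id in sorted(models):
        cov_df = covariances.get(gene_id) if covariances else None
        row, reason = _gene_association(
            models[gene_id], gwas_idx, harm.panel, cov_df, tissue, sigma_floor
        )
        if row is None:
            skipped.append({"gene_id": gene_id, "reason": reason})
        else:
            rows.append(row)
    return TissueResultSet(
        tissue=tissue,
        results=pd.DataFrame(rows, columns=RESULT_COLUMNS),
        skipped=pd.DataFrame(skipped, columns=["gene_id", "reason"]),
    )
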