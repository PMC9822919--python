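"""Study-wide significance accounting and focal-tissue exclusivity.

Results from many tissues for one phenotype are pooled; the Bonferroni
threshold is α divided by the total number of gene×tissue tests (not a
per-tissue count, since headline percentages are quoted against the pooled
total). Comparisons are strict ("p less than threshold"). A gene is
focal-tissue exclusive when it is Bonferroni-significant in the focal tissue
and in no other tissue where it was tested; genes with no model elsewhere
still count as exclusive but are distinguishable via ``tested_in_n_tissues``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .association import TissueResultSet


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def percent(k: int, n: int, decimals: int = 2) -> float:
    """Share of n expressed as a percentage, rounded for reporting."""
    return round(100.0 * k / n, decimals)


@dataclass
class PhenotypeSummary:
    phenotype: str
    results: pd.DataFrame  # pooled across tissues
    n_tests_total: int
    bonferroni: float
    alpha: float
    n_suggestive: int
    n_significant: int
    per_tissue: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        return self.results[self.results["pvalue"] < self.bonferroni]

    @property
    def suggestive(self) -> pd.DataFrame:
        return self.results[self.results["pvalue"] < self.alpha]

    def significant_genes(self, tissue: str) -> list[str]:
        sig = self.significant
        return sorted(sig.loc[sig["tissue"] == tissue, "gene_id"].unique())

    def tissues(self) -> list[str]:
        return sorted(self.results["tissue"].unique())


def classify(
    result_sets: list[TissueResultSet] | list[pd.DataFrame],
    phenotype: str = "",
    alpha: float = 0.05,
) -> PhenotypeSummary:
    """Pool per-tissue results and count suggestive / Bonferroni-significant tests."""
    frames = [
        rs.results if isinstance(rs, TissueResultSet) else rs for rs in result_sets
    ]
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene_id", "tissue", "pvalue"]
    )
    if pooled["pvalue"].isna().any():
        raise ValueError("every result must carry a p-value")
    if pooled.duplicated(subset=["gene_id", "tissue"]).any():
        dup = pooled[pooled.duplicated(subset=["gene_id", "tissue"])].iloc[0]
        raise ValueError(
            f"duplicate (gene, tissue) entry: {dup['gene_id']}/{dup['tissue']}"
        )
    n_total = len(pooled)
    thr = bonferroni_threshold(n_total, alpha) if n_total else float("nan")
    sugg = pooled["pvalue"] < alpha
    sig = pooled["pvalue"] < thr if n_total else sugg
    per_tissue = (
        pooled.assign(suggestive=sugg, significant=sig)
        .groupby("tissue")
        .agg(
            n_tests=("pvalue", "size"),
            n_suggestive=("suggestive", "sum"),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    return PhenotypeSummary(
        phenotype=phenotype,
        results=pooled,
        n_tests_total=n_total,
        bonferroni=thr,
        alpha=alpha,
        n_suggestive=int(sugg.sum()),
        n_significant=int(sig.sum()) if n_total else 0,
        per_tissue=per_tissue,
    )


def find_exclusive(summary: PhenotypeSummary, focal_tissue: str) -> pd.DataFrame:
    """Classify each focal-significant gene as tissue-exclusive or not.

    Returns one row per gene significant in the focal tissue with columns
    gene_id, focal_tissue, significant_in_focal, other_tissues_significant
    (comma-joined), exclusive, tested_in_n_tissues.
    """
    if focal_tissue not in set(summary.results["tissue"]):
        raise ValueError(f"focal tissue {focal_tissue!r} absent from results")
    sig = summary.significant
    focal_genes = summary.significant_genes(focal_tissue)
    tested_counts = summary.results.groupby("gene_id")["tissue"].nunique()
    rows = []
    for gene in focal_genes:
        others = sorted(
            sig.loc[(sig["gene_id"] == gene) & (sig["tissue"] != focal_tissue), "tissue"]
        )
        rows.append(
            {
                "gene_id": gene,
                "focal_tissue": focal_tissue,
                "significant_in_focal": True,
                "other_tissues_significant": ",".join(others),
                "exclusive": len(others) == 0,
                "tested_in_n_tissues": int(tested_counts.loc[gene]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "focal_tissue",
            "significant_in_focal",
            "other_tissues_significant",
            "exclusive",
            "tested_in_n_tissues",
        ],
    )


def overlap_phenotypes(
    summary_a: PhenotypeSummary,
    summary_b: PhenotypeSummary,
    focal_tissue: str,
) -> pd.DataFrame:
    """Genes focal-tissue exclusive for both phenotypes, with both effects."""
    excl_a = find_exclusive(summary_a, focal_tissue)
    excl_b = find_exclusive(summary_b, focal_tissue)
    shared = sorted(
        set(excl_a.loc[excl_a["exclusive"], "gene_id"])
        & set(excl_b.loc[excl_b["exclusive"], "gene_id"])
    )
    rows = []
    for gene in shared:
        ra = summary_a.results.query("gene_id == @gene and tissue == @focal_tissue").iloc[0]
        rb = summary_b.results.query("gene_id == @gene and tissue == @focal_tissue").iloc[0]
        rows.append(
            {
                "gene_id": gene,
                "effect_a": ra.get("effect"),
                "pvalue_a": ra["pvalue"],
                "effect_b": rb.get("effect"),
                "pvalue_b": rb["pvalue"],
                "consistent_direction": bool(ra.get("effect", 0) * rb.get("effect", 0) > 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "effect_a",
            "pvalue_a",
            "effect_b",
            "pvalue_b",
            "consistent_direction",
        ],
    )
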