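"""Readers, writers and allele harmonization for summary-statistic files.

All files are plain TSV with a header row. Coordinates are 1-based basepairs.
Gene identifiers are version-stripped (``ENSG0001.5`` -> ``ENSG0001``) before
any cross-source matching.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import LDPanel

logger = logging.getLogger(__name__)

# %.17g round-trips any float64 exactly through text
FLOAT_FMT = "%.17g"

GWAS_REQUIRED = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
]
GWAS_OPTIONAL = ["n", "zscore"]
EQTL_REQUIRED = ["gene_id"] + GWAS_REQUIRED

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing .N version suffix from an Ensembl-style gene ID."""
    return str(gene_id).split(".", 1)[0]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return {effect_allele, other_allele} in _PALINDROMIC_PAIRS


def _exact_float(s: pd.Series) -> pd.Series:
    """Coerce strings to float64 via float(), which round-trips %.17g exactly
    (pandas' own fast parser can be off by one ulp); failures become NaN."""

    def parse(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return float("nan")

    return s.map(parse).astype(float)


def _apply_column_map(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    if column_map:
        rename = {src: std for std, src in column_map.items()}
        df = df.rename(columns=rename)
    return df


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Coerce numeric columns and drop rows violating the record invariants.

    Returns the clean frame plus a reason -> count map of skipped rows.
    """
    skipped: dict[str, int] = {}
    n0 = len(df)
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = _exact_float(df[col])
    bad_numeric = df[["eaf", "beta", "se", "pvalue"]].isna().any(axis=1)
    if bad_numeric.any():
        skipped["non_numeric"] = int(bad_numeric.sum())
        df = df[~bad_numeric]
    bad_se = df["se"] <= 0
    if bad_se.any():
        skipped["nonpositive_se"] = int(bad_se.sum())
        df = df[~bad_se]
    bad_eaf = (df["eaf"] < 0) | (df["eaf"] > 1)
    if bad_eaf.any():
        skipped["eaf_out_of_range"] = int(bad_eaf.sum())
        df = df[~bad_eaf]
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    bad_alleles = (
        ~ea.isin(_VALID_ALLELES) | ~oa.isin(_VALID_ALLELES) | (ea == oa)
    )
    if bad_alleles.any():
        skipped["invalid_alleles"] = int(bad_alleles.sum())
        df = df[~bad_alleles]
    df = df.assign(
        effect_allele=df["effect_allele"].astype(str).str.upper(),
        other_allele=df["other_allele"].astype(str).str.upper(),
    )
    n_skipped = n0 - len(df)
    if n_skipped:
        logger.warning("skipped %d malformed rows: %s", n_skipped, skipped)
    return df.reset_index(drop=True), skipped


def read_gwas_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read GWAS summary statistics from TSV into a harmonizable frame.

    ``column_map`` maps standard names (keys) to the file's column names
    (values), e.g. ``{"pvalue": "P", "eaf": "FRQ"}``. The z-score is computed
    as beta/se when the file carries no ``zscore`` column. Malformed rows are
    skipped; the per-reason counts are stored in ``df.attrs["skipped"]``.
    """
    df = _apply_column_map(pd.read_csv(path, sep="\t", dtype=str), column_map)
    missing = [c for c in GWAS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS file {path} missing mandatory columns: {missing}")
    df, skipped = _validate_rows(df)
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    if "n" in df.columns:
        df["n"] = _exact_float(df["n"])
    if "zscore" in df.columns:
        df["zscore"] = _exact_float(df["zscore"]).fillna(df["beta"] / df["se"])
    else:
        df["zscore"] = df["beta"] / df["se"]
    df.attrs["skipped"] = skipped
    return df


def read_eqtl_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read per-tissue cis-eQTL summary statistics (one row per gene x variant).

    Gene IDs are version-stripped. Duplicate (gene_id, variant_id) pairs are a
    hard error because they would make the per-gene FDR and clumping ill-posed.
    """
    df = _apply_column_map(pd.read_csv(path, sep="\t", dtype=str), column_map)
    missing = [c for c in EQTL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"eQTL file {path} missing mandatory columns: {missing}")
    df["gene_id"] = df["gene_id"].map(strip_gene_version)
    df, skipped = _validate_rows(df)
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    dup = df.duplicated(subset=["gene_id", "variant_id"])
    if dup.any():
        pairs = df.loc[dup, ["gene_id", "variant_id"]].iloc[0].tolist()
        raise ValueError(f"duplicate (gene, variant) rows in {path}, first: {pairs}")
    df.attrs["skipped"] = skipped
    return df


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

@dataclass
class Harmonized:
    """GWAS rows aligned to the model effect alleles, plus the aligned panel."""

    gwas: pd.DataFrame
    panel: LDPanel | None
    counts: dict[str, int] = field(default_factory=dict)


def harmonize(
    gwas: pd.DataFrame,
    model_snps: pd.DataFrame,
    panel: LDPanel | None = None,
    drop_ambiguous: bool = True,
) -> Harmonized:
    """Align GWAS (and panel) effect alleles to the prediction-model alleles.

    For each model variant found in the GWAS: if the GWAS alleles match the
    model orientation the row is kept as is; if they are swapped, beta, z are
    sign-flipped and eaf replaced by 1-eaf; strand-ambiguous palindromic
    variants (A/T, C/G) are dropped when ``drop_ambiguous`` (default, since
    summary files carry no strand information); anything else is dropped as
    mismatched. Panel dosages are flipped where the panel counts the model's
    other allele. ``counts`` records retained/flipped/dropped tallies; the sum
    of retained and dropped model variants equals the model variant count.
    """
    snps = model_snps[["variant_id", "effect_allele", "other_allele"]].drop_duplicates(
        "variant_id"
    )
    counts = {
        "model_variants": len(snps),
        "retained": 0,
        "flipped": 0,
        "palindromic_dropped": 0,
        "mismatched": 0,
        "absent_from_gwas": 0,
        "absent_from_panel": 0,
    }
    merged = snps.merge(
        gwas, on="variant_id", how="left", suffixes=("_model", "")
    )
    absent = merged["beta"].isna()
    counts["absent_from_gwas"] = int(absent.sum())
    merged = merged[~absent]

    if panel is not None:
        in_panel = merged["variant_id"].isin(panel.variant_ids)
        counts["absent_from_panel"] = int((~in_panel).sum())
        merged = merged[in_panel]

    palindromic = merged.apply(
        lambda r: is_palindromic(r["effect_allele_model"], r["other_allele_model"]),
        axis=1,
    ) if len(merged) else pd.Series(dtype=bool)
    if drop_ambiguous and len(merged):
        counts["palindromic_dropped"] = int(palindromic.sum())
        merged = merged[~palindromic]

    direct = (merged["effect_allele"] == merged["effect_allele_model"]) & (
        merged["other_allele"] == merged["other_allele_model"]
    )
    swapped = (merged["effect_allele"] == merged["other_allele_model"]) & (
        merged["other_allele"] == merged["effect_allele_model"]
    )
    mismatched = ~(direct | swapped)
    counts["mismatched"] = int(mismatched.sum())
    merged = merged[~mismatched].copy()

    flip = (merged["effect_allele"] == merged["other_allele_model"]).to_numpy()
    merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    merged.loc[flip, "zscore"] = -merged.loc[flip, "zscore"]
    merged.loc[flip, "eaf"] = 1.0 - merged.loc[flip, "eaf"]
    merged["effect_allele"] = merged["effect_allele_model"]
    merged["other_allele"] = merged["other_allele_model"]
    counts["flipped"] = int(flip.sum())
    counts["retained"] = len(merged)

    out_cols = [c for c in merged.columns if not c.endswith("_model")]
    aligned = merged[out_cols].reset_index(drop=True)

    aligned_panel = panel
    if panel is not None and len(aligned):
        pvar = panel.variants.set_index("variant_id")
        present = [v for v in aligned["variant_id"] if v in panel]
        model_ea = aligned.set_index("variant_id")["effect_allele"]
        to_flip = [
            v
            for v in present
            if pvar.loc[v, "effect_allele"] == aligned.set_index("variant_id").loc[v, "other_allele"]
            and pvar.loc[v, "other_allele"] == model_ea.loc[v]
        ]
        aligned_panel = panel.flip(to_flip) if to_flip else panel
    return Harmonized(gwas=aligned, panel=aligned_panel, counts=counts)


# ---------------------------------------------------------------------------
# Model weight / covariance files (PredictDB-style weight + covariance pair)
# ---------------------------------------------------------------------------

WEIGHTS_COLUMNS = [
    "gene_id",
    "variant_id",
    "effect_allele",
    "other_allele",
    "weight",
    "eaf",
    "var_explained",
]
COVARIANCE_COLUMNS = ["gene_id", "variant_id_1", "variant_id_2", "covariance"]


def write_model_files(models, covariances, weights_path, covariance_path) -> None:
    """Write gene models as a weights TSV plus a pairwise-covariance TSV.

    ``models`` is a mapping gene_id -> GeneModel; ``covariances`` a mapping
    gene_id -> DataFrame with columns variant_id_1, variant_id_2, covariance.
    """
    wrows = []
    for gene_id, model in models.items():
        v = model.variants
        for _, r in v.iterrows():
            wrows.append(
                {
                    "gene_id": gene_id,
                    "variant_id": r["variant_id"],
                    "effect_allele": r["effect_allele"],
                    "other_allele": r["other_allele"],
                    "weight": r["weight"],
                    "eaf": r["eaf"],
                    "var_explained": r["var_explained"],
                }
            )
    pd.DataFrame(wrows, columns=WEIGHTS_COLUMNS).to_csv(
        weights_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    crows = []
    for gene_id, cov in covariances.items():
        known = set(models[gene_id].variants["variant_id"]) if gene_id in models else set()
        for _, r in cov.iterrows():
            if r["variant_id_1"] not in known or r["variant_id_2"] not in known:
                raise ValueError(
                    f"covariance entry for gene {gene_id} references variant absent "
                    f"from weights: {r['variant_id_1']}/{r['variant_id_2']}"
                )
            crows.append(
                {
                    "gene_id": gene_id,
                    "variant_id_1": r["variant_id_1"],
                    "variant_id_2": r["variant_id_2"],
                    "covariance": r["covariance"],
                }
            )
    pd.DataFrame(crows, columns=COVARIANCE_COLUMNS).to_csv(
        covariance_path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_model_files(weights_path, covariance_path):
    """Inverse of :func:`write_model_files`; round-trips to full precision."""
    from .models import GeneModel  # local import to avoid a cycle

    wdf = pd.read_csv(weights_path, sep="\t", float_precision="round_trip")
    cdf = pd.read_csv(covariance_path, sep="\t", float_precision="round_trip")
    missing = [c for c in WEIGHTS_COLUMNS if c not in wdf.columns]
    if missing:
        raise ValueError(f"weights file missing columns: {missing}")
    models: dict[str, GeneModel] = {}
    for gene_id, grp in wdf.groupby("gene_id", sort=True):
        models[gene_id] = GeneModel(
            gene_id=str(gene_id),
            tissue="",
            variants=grp.drop(columns="gene_id").reset_index(drop=True),
        )
    covariances: dict[str, pd.DataFrame] = {}
    for gene_id, grp in cdf.groupby("gene_id", sort=True):
        gene_id = str(gene_id)
        if gene_id not in models:
            raise ValueError(f"covariance rows for unknown gene {gene_id}")
        known = set(models[gene_id].variants["variant_id"])
        bad = grp[
            ~grp["variant_id_1"].isin(known) | ~grp["variant_id_2"].isin(known)
        ]
        if len(bad):
            raise ValueError(
                f"covariance entry for gene {gene_id} references variant absent "
                f"from weights: {bad.iloc[0]['variant_id_1']}/{bad.iloc[0]['variant_id_2']}"
            )
        covariances[gene_id] = grp.drop(columns="gene_id").reset_index(drop=True)
    return models, covariances


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
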