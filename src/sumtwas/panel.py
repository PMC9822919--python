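"""Reference genotype panel: dosages, frequencies, and LD.

The panel plays two roles downstream: it supplies the pairwise dosage
correlations used by LD clumping, and the dosage variances/covariances that
form the denominator of the summary-statistic association z-score.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "freq"]


@dataclass
class LDPanel:
    """Genotype dosages for a reference sample.

    Parameters
    ----------
    variants
        One row per variant with columns ``variant_id``, ``chrom``, ``pos``
        (1-based basepairs), ``effect_allele`` (the allele counted by the
        dosage), ``other_allele`` and ``freq`` (population frequency of the
        effect allele, informational; empirical frequencies are derived from
        the dosages).
    genotypes
        ``n_individuals x n_variants`` array of dosages in {0, 1, 2}, columns
        ordered as ``variants``.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    _col: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"panel variant table missing columns: {missing}")
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or g.shape[1] != len(self.variants):
            raise ValueError(
                f"genotypes shape {g.shape} does not match {len(self.variants)} variants"
            )
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        self.genotypes = g
        self.variants = self.variants.reset_index(drop=True)
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate variant_id in panel")
        self._col = {v: i for i, v in enumerate(ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._col

    def columns(self, variant_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._col[v] for v in variant_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in panel") from None

    def dosages(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Dosage matrix (individuals x requested variants), float64."""
        return self.genotypes[:, self.columns(variant_ids)].astype(float)

    # -- frequencies and LD ----------------------------------------------
    def empirical_freq(self, variant_ids: Sequence[str]) -> np.ndarray:
        return self.dosages(variant_ids).mean(axis=0) / 2.0

    def dosage_sd(self, variant_ids: Sequence[str], ddof: int = 1) -> np.ndarray:
        return self.dosages(variant_ids).std(axis=0, ddof=ddof)

    def covariance(self, variant_ids: Sequence[str], ddof: int = 1) -> np.ndarray:
        """Sample covariance matrix of the dosages (k x k)."""
        x = self.dosages(variant_ids)
        xc = x - x.mean(axis=0)
        return xc.T @ xc / (x.shape[0] - ddof)

    def r2(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Squared Pearson dosage correlation; 0 where a variant is monomorphic."""
        cov = self.covariance(variant_ids)
        sd = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = cov / np.outer(sd, sd)
        corr = np.nan_to_num(corr, nan=0.0)
        return corr**2

    # -- manipulation ----------------------------------------------------
    def subset(self, variant_ids: Sequence[str]) -> "LDPanel":
        idx = self.columns(variant_ids)
        return LDPanel(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx].copy(),
        )

    def flip(self, variant_ids: Sequence[str]) -> "LDPanel":
        """Swap the counted allele for the given variants (dosage -> 2 - dosage)."""
        idx = self.columns(variant_ids)
        geno = self.genotypes.copy()
        geno[:, idx] = 2 - geno[:, idx]
        var = self.variants.copy()
        ea = var.loc[idx, "effect_allele"].copy()
        var.loc[idx, "effect_allele"] = var.loc[idx, "other_allele"].to_numpy()
        var.loc[idx, "other_allele"] = ea.to_numpy()
        var.loc[idx, "freq"] = 1.0 - var.loc[idx, "freq"]
        return LDPanel(variants=var, genotypes=geno)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: variant metadata columns then one dosage column per sample."""
        samples = pd.DataFrame(
            self.genotypes.T,
            columns=[f"sample_{i + 1}" for i in range(self.n_individuals)],
        )
        pd.concat([self.variants.reset_index(drop=True), samples], axis=1).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )

    @classmethod
    def from_tsv(cls, path) -> "LDPanel":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        sample_cols = [c for c in df.columns if c.startswith("sample_")]
        if not sample_cols:
            raise ValueError("panel file has no sample_* dosage columns")
        geno = df[sample_cols].to_numpy().T
        return cls(variants=df[VARIANT_COLUMNS].copy(), genotypes=geno)
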