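"""Gene-set over-representation testing.

Enrichment of a query gene list against user-supplied sets is scored with the
upper-tail hypergeometric test: drawing n query genes from a background of N,
the probability of seeing at least the observed overlap k with a set of size
K is P(X >= k), X ~ Hypergeom(N, K, n). Set-level p-values are adjusted with
Benjamini-Hochberg across all tested sets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .models import fdr_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against.

    Genes in a set but outside the background are dropped with a warning so
    that the hypergeometric urn stays consistent.
    """

    sets: dict[str, list[str]]
    background: list[str]

    def __post_init__(self) -> None:
        bg = list(dict.fromkeys(self.background))
        if not bg:
            raise ValueError("background must be non-empty")
        bg_set = set(bg)
        clean = {}
        for name, genes in self.sets.items():
            genes = list(dict.fromkeys(genes))
            outside = [g for g in genes if g not in bg_set]
            if outside:
                logger.warning(
                    "set %s: dropping %d genes outside background", name, len(outside)
                )
            clean[name] = [g for g in genes if g in bg_set]
        self.sets = clean
        self.background = bg

    @classmethod
    def from_gmt(cls, path, background: list[str]) -> "GeneSetCollection":
        """Read GMT (set_name <tab> description <tab> gene1 <tab> gene2 ...)."""
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets=sets, background=background)


ENRICHMENT_COLUMNS = [
    "set_name",
    "overlap",
    "set_size",
    "query_size",
    "background_size",
    "pvalue",
    "p_adj",
    "genes",
]


def hypergeometric_enrichment(
    query: list[str],
    collection: GeneSetCollection,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Score every set in the collection against the query gene list.

    Query genes outside the background are dropped with a warning. Sets whose
    overlap with the query is below ``min_overlap`` are omitted. Returns a
    frame sorted by p-value with BH-adjusted values in ``p_adj``.
    """
    bg = set(collection.background)
    query = list(dict.fromkeys(query))
    unknown = [g for g in query if g not in bg]
    if unknown:
        logger.warning("dropping %d query genes outside background", len(unknown))
    query_set = {g for g in query if g in bg}
    if not query_set:
        logger.warning("empty query after background filtering")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    n = len(query_set)
    N = len(bg)
    rows = []
    for name, genes in collection.sets.items():
        members = set(genes)
        k = len(query_set & members)
        if k < min_overlap:
            continue
        K = len(members)
        pvalue = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "background_size": N,
                # clamp into (0, 1] so downstream BH stays well-posed even if
                # the tail sum under/overflows at double precision
                "pvalue": min(max(pvalue, 5e-324), 1.0),
                "genes": ",".join(sorted(query_set & members)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = pd.DataFrame(rows)
    out["p_adj"] = fdr_adjust(out["pvalue"].to_numpy())
    return out[ENRICHMENT_COLUMNS].sort_values(
        ["pvalue", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
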