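"""Over-representation of a significant-gene list in predefined gene sets.

Uses the upper-tail hypergeometric test with BH adjustment across sets, with
the background defaulting to all genes that had a prediction model.
"""
from sumtwas import GeneSetCollection, hypergeometric_enrichment

background = [f"GENE{i:03d}" for i in range(200)]
collection = GeneSetCollection(
    sets={
        "synaptic_transmission": background[:30],
        "lipid_metabolism": background[30:75],
        "ribosome": background[75:90],
    },
    background=background,
)
# a query enriched for the first set
query = background[:6] + background[100:106]

res = hypergeometric_enrichment(query, collection)
print(res[["set_name", "overlap", "set_size", "pvalue", "p_adj"]].to_string(index=False))
print(
    "\npvalue is P(X >= overlap) for X ~ Hypergeom(background, set, query); "
    "p_adj is Benjamini-Hochberg across the tested sets. Sets with zero "
    "overlap are omitted."
)
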