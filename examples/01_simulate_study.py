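"""Simulate a complete synthetic study: panel, eQTL and GWAS summary files.

Builds a small single-tissue scenario where one gene truly affects the trait,
writes all input files to ./scratch_example/, and prints what was generated.
"""
from sumtwas import SimScenario, write_scenario

scenario = SimScenario(
    seed=7,
    n_genes=10,
    m_variants=200,
    n_eqtl=1_000,
    n_gwas=5_000,
    true_genes={"SIMG00004": 0.25},  # trait effect per SD of this gene's GReX
)
paths = write_scenario(scenario, "scratch_example")

print("files written:")
for name, path in paths.items():
    print(f"  {name}: {path}")
print(
    f"\n{scenario.n_genes} genes x {scenario.m_variants} variants; "
    f"gene SIMG00004 carries a true effect of 0.25 trait SD per SD of its "
    "genetically regulated expression. The eQTL and GWAS files contain only "
    "marginal summary statistics; truth_*.tsv record the causal variants and "
    "effects the generators used, for validation."
)
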