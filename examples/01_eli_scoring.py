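"""Score genes by cross-species correlation with placental invasion.

Generates a 9-species fibroblast expression matrix with 10 genes planted to
track the invasion index (rho = 0.9), scores every gene, and selects those
above the 0.5 threshold.
"""

from invascope import eli, synthetic

expr, index, truth = synthetic.gen_species_expression(
    n_genes=1000, n_species=9, n_planted=10, rho=0.9, seed=1
)
table = eli.compute_eli_scores(expr, index, method="spearman")
selected = eli.select_eli_genes(table, threshold=0.5)

print("invasion index per species:")
print(index.to_string())
print("\ntop-scoring genes:")
print(table.sort_values("score", ascending=False).head(12).to_string(index=False))
recovered = set(truth.planted_eli_genes) & set(selected.members)
print(f"\nselected {len(selected)} genes with score > 0.5; "
      f"{len(recovered)}/10 planted genes recovered")
print("Scores near +-1 mean expression tracks invasion depth across species;")
print("selection above 0.5 keeps the planted genes plus the expected null tail.")
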