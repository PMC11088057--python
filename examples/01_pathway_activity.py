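"""Cell-type pathway activity with permutation significance.

Simulates a cohort in which one metabolic pathway is upregulated 2x in
one cell type, then recovers that program: the pathway's activity score
in the target type exceeds 1 (the no-enrichment baseline) and its
label-permutation p-value is small, while unplanted pathway/type pairs
hover around 1 with large p-values.
"""

import scmetland as sm

config = sm.SimulationConfig(
    n_genes=500,
    n_cells_per_type=(150, 150, 150),
    n_pathways=15,
    planted_effects=[("PATHWAY_05", "type_B", 2.0)],
    dropout_rate=0.3,
    seed=42,
)
matrix, annotation, gene_sets, truth = sm.generate_expression(config)
matrix = sm.impute(sm.log_transform(matrix), sm.PreprocessConfig(imputation="none"))

result = sm.permutation_test(matrix, annotation, gene_sets, n_perm=500, seed=1)
frame = result.to_long_frame()

print("Planted program (PATHWAY_05 up 2x in type_B):")
print(frame[frame["pathway"] == "PATHWAY_05"].to_string(index=False))
print()
top = frame.sort_values("p_value").head(5)
print("Most significant pathway/type pairs overall:")
print(top.to_string(index=False))
print()
print("score > 1 means the pathway sits above its across-type average in that type;")
print("'displayed' mirrors the heatmap convention of blanking p > 0.05 entries.")
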