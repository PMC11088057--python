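"""Which pathways drive metabolic heterogeneity?

Ranks metabolic genes by their PCA-loading variability score (sum of
absolute loadings over the components explaining >80% of variance) and
runs preranked GSEA on that ranking. The pathway with the planted
cell-type program contributes the most variable genes, so it surfaces
with the top normalized enrichment score.
"""

import scmetland as sm

config = sm.SimulationConfig(
    n_genes=500,
    n_cells_per_type=(100, 100, 100),
    n_pathways=12,
    planted_effects=[("PATHWAY_05", "type_B", 4.0)],
    dropout_rate=0.2,
    seed=21,
)
matrix, annotation, gene_sets, _ = sm.generate_expression(config)
matrix = sm.log_transform(matrix)

metabolic_genes = sorted({g for s in gene_sets.metabolic_sets.values() for g in s})
pca = sm.pca_gene_scores(matrix, genes=metabolic_genes)
print(f"components selected: {pca.n_components_selected} "
      f"(cumulative variance {pca.cumulative_variance:.3f})")

ranked = sm.rank_genes(pca)
print("\nmost variable metabolic genes:")
print(ranked.head(5).to_string(index=False))

gsea = sm.gsea_preranked(ranked, gene_sets, n_perm=500, seed=0)
print("\npathways enriched among high-variability genes (top 5 by NES):")
print(gsea.table.head(5)[["set", "size", "es", "nes", "p_value", "p_adjusted"]]
      .to_string(index=False))
print("\nThe planted pathway (PATHWAY_05) tops the list: its genes vary")
print("most across cells because one cell type carries the 4x program.")
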