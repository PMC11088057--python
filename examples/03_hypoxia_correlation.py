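"""Hypoxia-glycolysis coupling at single-cell resolution.

The generator plants a latent per-cell hypoxia factor loaded onto both
the hallmark hypoxia signature and the glycolysis pathway at a target
correlation of 0.8. Per-cell signature scores (mean of per-gene
z-scores) recover that coupling within each cell type.
"""

import numpy as np

import scmetland as sm
from scmetland.synthetic import GLYCOLYSIS_SET_NAME, HYPOXIA_SET_NAME

config = sm.SimulationConfig(
    n_genes=400,
    n_cells_per_type=(250, 250),
    n_pathways=8,
    hypoxia_rho=0.8,
    seed=4,
)
matrix, annotation, gene_sets, truth = sm.simulate(config)

hyp = matrix.values[matrix.gene_indexer(gene_sets[HYPOXIA_SET_NAME])].mean(axis=0)
gly = matrix.values[matrix.gene_indexer(gene_sets[GLYCOLYSIS_SET_NAME])].mean(axis=0)
print(f"correlation of raw per-cell set means: {np.corrcoef(hyp, gly)[0, 1]:.3f} "
      f"(target {config.hypoxia_rho})")

prepped = sm.impute(
    sm.log_transform(matrix),
    sm.PreprocessConfig(imputation="knn_smooth", k_neighbors=10),
    annotation,
)
scores = sm.CellSignatureScores.compute(prepped, {
    "hypoxia": gene_sets[HYPOXIA_SET_NAME],
    "glycolysis": gene_sets[GLYCOLYSIS_SET_NAME],
})
table = sm.correlate_by_type(scores, annotation, method="spearman")
print("\nper-cell-type Spearman correlation of signature scores:")
print(table.to_string(index=False))
print("\nr near 0.8 in every type shows the per-cell scoring pipeline recovers")
print("the planted hypoxia-glycolysis coupling after imputation.")
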