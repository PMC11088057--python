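import numpy as np
import pandas as pd
import pytest

from scmetland import CellAnnotation, ExpressionMatrix, GeneSetCollection, SimulationConfig, generate_expression


@pytest.fixture(scope="session")
def small_null_sim():
    """Small simulated dataset with no planted effects (shared, read-only)."""
    cfg = SimulationConfig(
        n_genes=300, n_cells_per_type=(60, 60, 60), n_pathways=8,
        genes_per_pathway=10, dropout_rate=0.2, seed=42,
    )
    return generate_expression(cfg)


@pytest.fixture
def tiny_matrix():
    """Deterministic 5-gene x 6-cell matrix over 3 cell types (2 cells each)."""
    rng = np.random.default_rng(0)
    values = rng.uniform(0.5, 5.0, size=(5, 6))
    genes = [f"g{i}" for i in range(5)]
    cells = [f"c{i}" for i in range(6)]
    matrix = ExpressionMatrix(values, genes, cells, stage="log2tpm1")
    ann = CellAnnotation(pd.DataFrame({
        "sample_id": "s1",
        "tissue_group": "tumor",
        "cell_type": ["A", "A", "B", "B", "C", "C"],
    }, index=pd.Index(cells)))
    return matrix, ann


@pytest.fixture
def tiny_sets():
    """Two overlapping 3-gene metabolic sets over the tiny matrix's genes."""
    return GeneSetCollection({"P1": ("g0", "g1", "g2"), "P2": ("g2", "g3", "g4")})
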