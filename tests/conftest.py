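import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scpool import (
    CellAnnotation,
    GeneExpressionMatrix,
    SimulationConfig,
    BlockConfig,
    ProportionSimConfig,
    simulate_dataset,
)


@pytest.fixture
def toy_matrix():
    """3 cells x 2 genes with a single nonzero entry."""
    counts = sp.csr_matrix(np.array([[4, 0], [0, 0], [0, 0]]))
    return GeneExpressionMatrix(
        counts=counts,
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
        gene_ids=np.array(["g1", "g2"], dtype=object),
        gene_symbols=np.array(["G1", "G2"], dtype=object),
    )


@pytest.fixture
def toy_annotation():
    table = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "donor": ["J-01", "J-01", "C-01"],
            "batch": ["1", "1", "2"],
            "stimulus": ["TNF", "Null", "TNF"],
            "status": ["JIA", "JIA", "Control"],
            "cluster": ["T", "T", "B"],
        }
    )
    return CellAnnotation(table)


def make_matrix(counts, cell_prefix="c", gene_prefix="g", gene_symbols=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    return GeneExpressionMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=np.array([f"{cell_prefix}{i}" for i in range(n_cells)], dtype=object),
        gene_ids=np.array([f"{gene_prefix}{j}" for j in range(n_genes)], dtype=object),
        gene_symbols=(
            np.array(gene_symbols, dtype=object) if gene_symbols is not None else None
        ),
    )


def make_annotation(n_cells, clusters=None, donors=None, cell_prefix="c", **extra_cols):
    clusters = clusters if clusters is not None else ["T"] * n_cells
    donors = donors if donors is not None else ["J-01"] * n_cells
    batch = {"J-01": "1", "J-02": "1", "C-01": "2"}
    status = {"J-01": "JIA", "J-02": "JIA", "C-01": "Control"}
    table = pd.DataFrame(
        {
            "cell_id": [f"{cell_prefix}{i}" for i in range(n_cells)],
            "donor": donors,
            "batch": [batch.get(d, "1") for d in donors],
            "stimulus": ["TNF"] * n_cells,
            "status": [status.get(d, "JIA") for d in donors],
            "cluster": clusters,
        }
    )
    label_cols = []
    for name, values in extra_cols.items():
        table[name] = values
        label_cols.append(name)
    return CellAnnotation(table, tuple(label_cols))


@pytest.fixture(scope="session")
def small_dataset():
    """A small full dataset exercising mito and label-noise corruptions."""
    cfg = SimulationConfig(
        n_cell_types=3,
        cells_per_sample=40,
        n_genes=60,
        blocks=(BlockConfig(60, {"donor": 0.3}),),
        n_mito_genes=3,
        mito_high_frac=0.05,
        label_noise_frac=0.1,
        library_size=800.0,
        seed=123,
    )
    matrix, annotation, truth = simulate_dataset(cfg)
    return cfg, matrix, annotation, truth
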