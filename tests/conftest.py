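import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse


def make_annotation(n_genes, mito=(), lengths=None, orthologs=None, gate_index=None):
    """Small hand-built annotation table for fixtures."""
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    symbols = []
    for i, gid in enumerate(gene_ids):
        if gate_index is not None and i == gate_index:
            symbols.append("Alb")
        elif i in set(mito):
            symbols.append(f"mt-G{i + 1}")
        else:
            symbols.append(f"G{i + 1}")
    if lengths is None:
        lengths = np.full(n_genes, 1000, dtype=np.int64)
    if orthologs is None:
        orthologs = symbols
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "length_bp": np.asarray(lengths, dtype=np.int64),
            "is_mitochondrial": [i in set(mito) for i in range(n_genes)],
            "ortholog_symbol": pd.array(orthologs, dtype="string"),
        }
    )


def make_counts(dense, annotation=None, cell_ids=None):
    """Wrap a dense integer array as the cells x genes AnnData the package uses."""
    dense = np.asarray(dense)
    n_cells, n_genes = dense.shape
    if annotation is None:
        annotation = make_annotation(n_genes)
    if cell_ids is None:
        cell_ids = [f"cell_{i + 1:04d}" for i in range(n_cells)]
    var = annotation.set_index("gene_id", drop=False)
    var.index.name = None
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    return AnnData(X=sparse.csr_matrix(dense.astype(np.int64)), obs=obs, var=var)


def random_fixture(rng, n_cells=30, n_genes=40, n_mito=4):
    """A random sparse-ish count matrix plus matching annotation."""
    dense = rng.poisson(1.2, size=(n_cells, n_genes)) * (rng.random((n_cells, n_genes)) < 0.6)
    mito = list(range(n_genes - n_mito, n_genes))
    lengths = rng.integers(300, 10001, size=n_genes)
    orthologs = [None if rng.random() < 0.2 else f"G{i + 1}" for i in range(n_genes)]
    annotation = make_annotation(n_genes, mito=mito, lengths=lengths, orthologs=orthologs)
    return make_counts(dense.astype(np.int64), annotation), annotation, dense.astype(np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_sim_config():
    from agescreen import SimulationConfig

    return SimulationConfig(
        n_cells_young=60,
        n_cells_old=120,
        n_genes=300,
        n_mito_genes=8,
        seed=11,
    )
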