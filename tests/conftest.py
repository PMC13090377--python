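import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from singulor import CountMatrix, SimulationConfig, simulate_cohort


def make_gene_table(gene_ids, **overrides):
    """Minimal valid gene annotation for hand-built matrices."""
    n = len(gene_ids)
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": gene_ids,
            "is_or": [False] * n,
            "or_class": ["none"] * n,
            "chromosome": ["chr1"] * n,
            "marker_role": ["none"] * n,
        }
    )
    for col, vals in overrides.items():
        df[col] = vals
    return df


def make_cell_table(cell_ids, **overrides):
    n = len(cell_ids)
    df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "donor": ["D01"] * n,
            "stage": ["PCW7"] * n,
            "cell_type": ["iOSN"] * n,
            "modality": ["snrna"] * n,
        }
    )
    for col, vals in overrides.items():
        df[col] = vals
    return df


def make_count_matrix(dense, cell_ids=None, gene_ids=None):
    dense = np.asarray(dense)
    n, m = dense.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(m)]
    return CountMatrix(np.array(cell_ids, dtype=object), np.array(gene_ids, dtype=object),
                       sp.csr_matrix(dense))


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort with 2% planted contamination."""
    cfg = SimulationConfig(seed=0, contamination_fraction=0.02)
    cm, genes, cells, truth = simulate_cohort(cfg)
    return cfg, cm, genes, cells, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Small clean cohort without contamination, reduced gene panel."""
    cfg = SimulationConfig(seed=1, n_background_genes=200)
    cm, genes, cells, truth = simulate_cohort(cfg)
    return cfg, cm, genes, cells, truth
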