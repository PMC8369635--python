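import numpy as np
import pytest
import scipy.sparse as sp

from cocoadiff.io import CellCountMatrix, CellMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_counts(Y, gene_prefix="g", cell_prefix="c") -> CellCountMatrix:
    Y = np.asarray(Y)
    return CellCountMatrix(
        counts=sp.csr_matrix(Y),
        gene_ids=[f"{gene_prefix}{i}" for i in range(Y.shape[0])],
        cell_ids=[f"{cell_prefix}{j}" for j in range(Y.shape[1])],
    )


def make_meta(cell_ids, cell_ind, labels) -> CellMeta:
    """labels: per-individual 0/1 list; cell_ind: individual index per cell."""
    ind_ids = [f"i{i}" for i in range(len(labels))]
    return CellMeta(
        individual_of={c: ind_ids[i] for c, i in zip(cell_ids, cell_ind)},
        label_of={ind_ids[i]: int(labels[i]) for i in range(len(labels))},
    )


@pytest.fixture
def small_cohort():
    """A modest simulated cohort shared across structural tests."""
    from cocoadiff.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_genes=200, n_causal=10, n_individuals=10, cells_per_individual=20,
        var_xw=0.5, var_wy=0.3, var_xby=0.5, d_confounders=2, seed=7,
    )
    return simulate_dataset(cfg)
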