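"""Shared fixtures: one default simulated dataset (expensive) reused across
modules, plus small helper builders."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from krassig import (
    CountMatrix,
    QCConfig,
    SimConfig,
    apply_qc_filters,
    generate_sc_dataset,
    normalize_log,
    size_factors,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Simulated matrix + ground truth at the generator's default conditions."""
    return generate_sc_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def qc_result(default_dataset):
    matrix, _ = default_dataset
    return apply_qc_filters(matrix, QCConfig(seed=0))


@pytest.fixture(scope="session")
def normalized(qc_result):
    filtered, _, _ = qc_result
    factors = size_factors(filtered)
    return normalize_log(filtered, factors), factors


def build_matrix(counts, gene_ids=None, cell_ids=None) -> CountMatrix:
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids or [f"G{i:04d}" for i in range(n_genes)],
        cell_ids=cell_ids or [f"C{i:04d}" for i in range(n_cells)],
    )


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(0)
    return build_matrix(rng.poisson(2.0, size=(50, 50)))
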