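import numpy as np
import pandas as pd
import pytest

from scstress.io import ExpressionMatrix, GeneModelSet, ReadPlacementTable
from scstress.synth import SimConfig, simulate_gene_models, simulate_read_placements


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, fully-featured configuration for unit tests."""
    return SimConfig(seed=42, n_genes=60, n_cells_per_group=4, mean_depth=4000)


@pytest.fixture(scope="session")
def small_models(small_config) -> GeneModelSet:
    return simulate_gene_models(small_config)


@pytest.fixture(scope="session")
def small_placements(small_config, small_models) -> ReadPlacementTable:
    table, _ = simulate_read_placements(small_models, small_config)
    return table


@pytest.fixture
def toy_models() -> GeneModelSet:
    """Two genes on one reference with hand-checkable coordinates."""
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "ref": ["chr1", "chr1"],
        "start": [101, 401],
        "end": [200, 500],
        "strand": ["+", "-"],
    })
    return GeneModelSet(genes, ref_lengths={"chr1": 700})


def make_placements(rows) -> ReadPlacementTable:
    """Rows of (cell, ref, start, length, strand, cls) -> table."""
    return ReadPlacementTable(pd.DataFrame(
        rows, columns=["cell_id", "ref", "start", "length", "strand", "read_class"]
    ))


@pytest.fixture
def counts_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[10.0, 0.0, 3.0], [10.0, 5.0, 0.0], [0.0, 5.0, 7.0]],
        index=["g1", "g2", "g3"], columns=["c1", "c2", "c3"],
    )
    lengths = pd.Series([1000.0, 2000.0, 500.0], index=values.index)
    return ExpressionMatrix(values, "counts", gene_lengths=lengths)
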