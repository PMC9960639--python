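"""Quantification units, gene filtering, and cell-level structure.

TPM normalizes counts by gene length then scales each cell to one million;
CPM scales raw counts to one million. Cell-level structure follows the usual
workflow for full-length scRNA-seq: per-gene-centered PCA on log2(TPM+1),
and complete-linkage clustering of cells on 1 − Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from scstress.io import ExpressionMatrix

__all__ = [
    "CellEmbedding",
    "CellDendrogram",
    "compute_tpm",
    "compute_cpm",
    "filter_genes",
    "log_transform",
    "pca_embed",
    "cell_cluster",
]


@dataclass
class CellEmbedding:
    """PCA scores for cells plus explained-variance fractions."""

    scores: pd.DataFrame            # cells × k
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame | None = None   # genes × k

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")


@dataclass
class CellDendrogram:
    """Agglomerative merge tree over cells (scipy linkage encoding)."""

    linkage: np.ndarray
    cell_ids: list[str]
    method: str = "complete"

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.cell_ids, name="cluster")

    def to_newick(self) -> str:
        """Newick string with linkage heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def build(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.cell_ids[node.id]}:{length:.6g}"
            left = build(node.left, node.dist)
            right = build(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return build(tree, tree.dist) + ";"


def compute_tpm(
    counts: ExpressionMatrix, lengths: pd.Series | None = None
) -> ExpressionMatrix:
    """Transcripts per million: TPM_g = (c_g/l_g) / Σ_j(c_j/l_j) × 10⁶.

    Lengths are in bp (the matrix's own ``gene_lengths`` by default). Cells
    with zero total yield all-zero columns. Every non-zero column sums to
    10⁶ exactly up to floating-point rounding.
    """
    lengths = lengths if lengths is not None else counts.gene_lengths
    if lengths is None:
        raise ValueError("gene lengths required for TPM")
    lengths = lengths.reindex(counts.values.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)][0]
        raise ValueError(f"missing or non-positive length for gene {bad!r}")
    rate = counts.values.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    tpm = rate.div(totals.where(totals > 0, 1.0), axis=1) * 1e6
    return ExpressionMatrix(tpm, "TPM", gene_lengths=lengths, cell_meta=counts.cell_meta)


def compute_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million (cells with zero total give all-zero columns)."""
    totals = counts.values.sum(axis=0)
    cpm = counts.values.div(totals.where(totals > 0, 1.0), axis=1) * 1e6
    return ExpressionMatrix(cpm, "CPM", gene_lengths=counts.gene_lengths,
                            cell_meta=counts.cell_meta)


def filter_genes(matrix: ExpressionMatrix, min_detect_frac: float = 0.2) -> list[str]:
    """Genes with a non-zero value in at least ⌈frac · n_cells⌉ cells.

    "At least 20% of cells" is inclusive: with 10 cells and frac 0.2 a gene
    detected in exactly 2 cells is kept.
    """
    n_cells = matrix.shape[1]
    need = math.ceil(min_detect_frac * n_cells)
    detected = (matrix.values > 0).sum(axis=1)
    return detected.index[detected >= need].tolist()


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1) on a TPM matrix."""
    if matrix.unit != "TPM":
        raise ValueError(f"log_transform expects TPM input, got {matrix.unit}")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), "log2TPM1",
                            gene_lengths=matrix.gene_lengths, cell_meta=matrix.cell_meta)


def pca_embed(matrix: ExpressionMatrix, k: int = 2, scale: bool = False) -> CellEmbedding:
    """Per-gene-centered PCA of cells; deterministic up to a fixed sign.

    The sign of each component is fixed by making its largest-magnitude gene
    loading positive. ``scale=True`` additionally divides each gene by its
    standard deviation (constant genes are left centered at zero).
    """
    X = matrix.values.to_numpy(dtype=float).T  # cells × genes
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise ValueError("PCA needs at least 2 cells")
    if k > min(n_genes, n_cells - 1):
        raise ValueError(f"k={k} exceeds min(genes, cells-1)")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        Xc = np.divide(Xc, np.where(sd > 0, sd, 1.0))
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(min(k, Vt.shape[0])):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        (U[:, :k] * S[:k]), index=matrix.cell_ids,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    loadings = pd.DataFrame(
        Vt[:k].T, index=matrix.gene_ids, columns=scores.columns
    )
    return CellEmbedding(scores, evr[:k], loadings)


def cell_cluster(matrix: ExpressionMatrix, method: str = "complete") -> CellDendrogram:
    """Complete-linkage clustering of cells on 1 − Pearson correlation.

    A constant cell expression vector has undefined correlation and raises,
    naming the cell. Ties in merge order follow scipy's deterministic
    ordering of the (cell-id-ordered) condensed distance matrix.
    """
    X = matrix.values.to_numpy(dtype=float).T
    cells = matrix.cell_ids
    if len(cells) < 2:
        raise ValueError("clustering needs at least 2 cells")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = cells[int(np.argmax(sd == 0))]
        raise ValueError(f"cell {bad!r} has constant expression; correlation undefined")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return CellDendrogram(Z, cells, method)
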