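"""Variability-driven gene modules and their regulating TFs.

Within one (condition, batch) stratum, genes expressed in enough cells are
clustered on the absolute-Pearson-correlation distance 1 − |r| with Ward
linkage ('ward.D2' convention: squared-dissimilarity update on the supplied
distance). The number of clusters is chosen by mean silhouette over a
candidate range — a deliberate, recorded stand-in for the NbClust index
battery used in the original workflow. Each cluster is then assigned the
most significantly enriched TF (hypergeometric test against a curated
TF→target table, BH across TFs within the cluster) when its adjusted
p-value clears the significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from scstress.de import bh_adjust
from scstress.io import ExpressionMatrix, TFInteractionTable

__all__ = ["GeneClustering", "gene_distance", "cluster_genes", "assign_cluster_tfs"]

#: below this best mean silhouette the partition is reported as weak structure
WEAK_SILHOUETTE = 0.1


@dataclass
class GeneClustering:
    """A gene partition with the evidence used to choose it."""

    labels: pd.Series                      # gene -> cluster id (1-based)
    chosen_k: int
    selection_scores: dict[int, float]     # candidate k -> mean silhouette
    linkage: np.ndarray
    method: str = "ward.D2 on 1-|r| distance; k by mean silhouette"
    weak_structure: bool = False
    tf_assignments: pd.DataFrame | None = None

    def members(self, cluster: int) -> set[str]:
        return set(self.labels.index[self.labels == cluster])

    @property
    def clusters(self) -> list[int]:
        return sorted(self.labels.unique())


def gene_distance(
    matrix: ExpressionMatrix, min_detect_frac: float = 0.10
) -> pd.DataFrame:
    """Absolute-correlation distance d = 1 − |Pearson r| between genes.

    Genes with a non-zero value in fewer than ⌈frac · n_cells⌉ cells are
    dropped first; constant genes (undefined correlation) are excluded with
    a warning. The result is symmetric with a zero diagonal, values in
    [0, 1].
    """
    V = matrix.values
    n_cells = V.shape[1]
    need = int(np.ceil(min_detect_frac * n_cells))
    keep = (V > 0).sum(axis=1) >= need
    V = V.loc[keep]
    sd = V.std(axis=1, ddof=0)
    if (sd == 0).any():
        dropped = sd.index[sd == 0].tolist()
        warnings.warn(f"excluding {len(dropped)} constant gene(s): {dropped[:5]}")
        V = V.loc[sd > 0]
    if V.shape[0] < 2:
        raise ValueError("fewer than 2 genes pass the detection filter")
    corr = np.corrcoef(V.to_numpy(dtype=float))
    d = 1.0 - np.abs(corr)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(d, index=V.index, columns=V.index)


def cluster_genes(
    distance: pd.DataFrame, k_range: tuple[int, int] = (2, 200)
) -> GeneClustering:
    """Ward clustering of genes; k maximizes mean silhouette over ``k_range``.

    Ties in the silhouette score break toward smaller k. When even the best
    score is below ``WEAK_SILHOUETTE`` the partition has no convincing
    structure: the smallest candidate k is returned and flagged.
    """
    genes = distance.index.tolist()
    n = len(genes)
    if n < 3:
        raise ValueError("need at least 3 genes to cluster")
    lo = max(2, k_range[0])
    hi = min(k_range[1], n - 1)
    if lo > hi:
        raise ValueError(f"k_range {k_range} incompatible with {n} genes")
    D = distance.to_numpy(dtype=float)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    scores: dict[int, float] = {}
    best_k, best_score = lo, -np.inf
    for k in range(lo, hi + 1):
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = float(silhouette_score(D, labels, metric="precomputed"))
        scores[k] = s
        if s > best_score + 1e-12:
            best_k, best_score = k, s
    weak = best_score < WEAK_SILHOUETTE
    if weak:
        best_k = lo
    labels = pd.Series(
        hierarchy.fcluster(Z, t=best_k, criterion="maxclust"), index=genes, name="cluster"
    )
    return GeneClustering(labels, best_k, scores, Z, weak_structure=weak)


def assign_cluster_tfs(
    clustering: GeneClustering,
    known: TFInteractionTable,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign each cluster its most enriched TF when BH-adjusted p < alpha.

    Per cluster, every TF's curated target set is tested against the cluster
    members with an upper-tail hypergeometric test over ``universe``; BH
    adjustment is across TFs within the cluster. Exact ties on adjusted p
    break deterministically by TF id and are recorded. The result is stored
    on the clustering and returned.
    """
    if len(known) == 0:
        raise ValueError("empty TF interaction table")
    universe = set(universe)
    M = len(universe)
    target_sets = {tf: tg & universe for tf, tg in known.target_sets().items()}
    rows = []
    for cluster in clustering.clusters:
        members = clustering.members(cluster) & universe
        N = len(members)
        tf_rows = []
        for tf in sorted(target_sets):
            tset = target_sets[tf]
            k = len(tset & members)
            n = len(tset)
            from scipy.stats import hypergeom
            p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
            tf_rows.append((tf, k, n, min(p, 1.0)))
        tf_table = pd.DataFrame(tf_rows, columns=["tf_id", "overlap", "set_size", "p_value"])
        tf_table["fdr"] = bh_adjust(tf_table["p_value"])
        best = tf_table.sort_values(["fdr", "tf_id"]).iloc[0]
        tied = tf_table[np.isclose(tf_table["fdr"], best["fdr"])]["tf_id"].tolist()
        assigned = best["tf_id"] if best["fdr"] < alpha else None
        rows.append({
            "cluster": cluster, "size": N, "assigned_tf": assigned,
            "fdr": float(best["fdr"]), "overlap": int(best["overlap"]),
            "tied_tfs": ",".join(tied) if len(tied) > 1 and assigned else "",
            "tf_in_cluster": bool(assigned in members) if assigned else False,
        })
    out = pd.DataFrame(rows).set_index("cluster")
    clustering.tf_assignments = out
    return out
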